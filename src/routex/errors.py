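"""Exception and warning types shared across the package."""


class RoutexError(Exception):
    """Base class for all routex errors."""


class InvalidParameterError(RoutexError, ValueError):
    """A parameter is outside its admissible range."""


class EmptySupportError(RoutexError):
    """A forcing region contains no triangle barycenter."""


class UnbalancedForcingError(RoutexError):
    """The forcing does not sum to zero, making the Neumann problem singular."""


class InvalidStateError(RoutexError):
    """An internal field violates an invariant (e.g. non-positive conductivity)."""


class NumericalFailureError(RoutexError):
    """A numerical update produced NaN/Inf; reports the iteration it occurred at."""


class TerminalSelectionError(RoutexError):
    """No eligible source or sink node exists on the extracted graph."""


class FitFailureError(RoutexError):
    """A distribution fit could not be performed (degenerate data)."""


class EmptyGraphWarning(UserWarning):
    """A selection or pruning step produced an empty graph."""


class ContestedTerminalWarning(UserWarning):
    """A node was eligible as both source and sink and was assigned to neither."""
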