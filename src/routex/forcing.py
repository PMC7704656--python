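"""Source/sink (forcing) specifications and their discretisation.

The forcing ``f = f⁺ − f⁻`` injects mass in source regions and removes it
in sink regions; the system is isolated, so ``∫_Ω f dx = 0``.  Regions are
simple geometric shapes (axis-aligned rectangles, disks, annuli); a
triangle belongs to a region iff its barycenter does.  After rasterising,
source and sink masses are independently rescaled to +1 and −1, which
enforces exact discrete mass balance regardless of how the region areas
are resolved by the mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySupportError, InvalidParameterError
from .mesh import TriangularMesh

__all__ = [
    "Rectangle",
    "Disk",
    "Annulus",
    "ForcingSpec",
    "ForcingField",
    "evaluate_forcing",
]


@dataclass
class Rectangle:
    """Axis-aligned closed rectangle [xmin, xmax] × [ymin, ymax]."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    sign: int = 1
    rate: float = 1.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return (
            (p[:, 0] >= self.xmin)
            & (p[:, 0] <= self.xmax)
            & (p[:, 1] >= self.ymin)
            & (p[:, 1] <= self.ymax)
        )

    def to_dict(self) -> dict:
        return {"shape": "rectangle", "xmin": float(self.xmin), "ymin": float(self.ymin),
                "xmax": float(self.xmax), "ymax": float(self.ymax),
                "sign": int(self.sign), "rate": float(self.rate)}


@dataclass
class Disk:
    """Closed disk of radius ``radius`` centred at (cx, cy)."""

    cx: float
    cy: float
    radius: float
    sign: int = 1
    rate: float = 1.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        d2 = (p[:, 0] - self.cx) ** 2 + (p[:, 1] - self.cy) ** 2
        return d2 <= self.radius**2

    def to_dict(self) -> dict:
        return {"shape": "disk", "cx": float(self.cx), "cy": float(self.cy),
                "radius": float(self.radius), "sign": int(self.sign), "rate": float(self.rate)}


@dataclass
class Annulus:
    """Half-open annulus: inner < r ≤ outer around (cx, cy).

    The inner boundary is excluded so a disk of radius ``inner`` and this
    annulus partition the outer disk without overlap.
    """

    cx: float
    cy: float
    inner: float
    outer: float
    sign: int = 1
    rate: float = 1.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        d2 = (p[:, 0] - self.cx) ** 2 + (p[:, 1] - self.cy) ** 2
        return (d2 > self.inner**2) & (d2 <= self.outer**2)

    def to_dict(self) -> dict:
        return {"shape": "annulus", "cx": float(self.cx), "cy": float(self.cy),
                "inner": float(self.inner), "outer": float(self.outer),
                "sign": int(self.sign), "rate": float(self.rate)}


_SHAPES = {"rectangle": Rectangle, "disk": Disk, "annulus": Annulus}


@dataclass
class ForcingSpec:
    """A list of signed regions; must contain ≥1 source and ≥1 sink."""

    regions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        signs = {int(np.sign(r.sign)) for r in self.regions}
        if not {1, -1} <= signs:
            raise InvalidParameterError(
                "forcing spec needs at least one source (+1) and one sink (-1) region"
            )
        for r in self.regions:
            if r.rate <= 0:
                raise InvalidParameterError("region rate must be positive")

    @property
    def sources(self) -> list:
        return [r for r in self.regions if r.sign > 0]

    @property
    def sinks(self) -> list:
        return [r for r in self.regions if r.sign < 0]

    def to_dict(self) -> dict:
        return {"regions": [r.to_dict() for r in self.regions]}

    @classmethod
    def from_dict(cls, data: dict) -> "ForcingSpec":
        regions = []
        for rd in data["regions"]:
            rd = dict(rd)
            shape = rd.pop("shape")
            regions.append(_SHAPES[shape](**rd))
        return cls(regions)


@dataclass
class ForcingField:
    """Per-triangle integrated mass f_i (density × area); sums to zero."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def source_mask(self) -> np.ndarray:
        return self.values > 0

    @property
    def sink_mask(self) -> np.ndarray:
        return self.values < 0


def evaluate_forcing(mesh: TriangularMesh, spec: ForcingSpec) -> ForcingField:
    """Rasterise a forcing spec onto a mesh with exact discrete balance.

    Each triangle whose barycenter lies in a region receives
    ``rate · area``; source and sink contributions are then separately
    rescaled so the totals are +1 and −1.  Raises
    :class:`EmptySupportError` if any region captures no barycenter.
    """
    b = mesh.barycenters
    plus = np.zeros(mesh.n_triangles)
    minus = np.zeros(mesh.n_triangles)
    for k, region in enumerate(spec.regions):
        inside = region.contains(b)
        if not inside.any():
            raise EmptySupportError(
                f"region #{k} ({type(region).__name__}, sign={region.sign:+d}) "
                "contains no triangle barycenter; refine the mesh or enlarge the region"
            )
        contrib = region.rate * mesh.areas * inside
        if region.sign > 0:
            plus += contrib
        else:
            minus += contrib
    values = plus / plus.sum() - minus / minus.sum()
    return ForcingField(values)
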