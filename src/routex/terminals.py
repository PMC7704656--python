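"""Source/sink node selection on the pre-extracted graph.

Every graph node whose position lies in the support of f⁺ (resp. f⁻) is
*eligible* as a source (resp. sink).  Among the eligible nodes we keep
the representative ones: vertices of the 2D convex hull of the eligible
positions (they trace the outer shape of the region) and nodes whose
normalised shortest-path betweenness centrality is below τ_BC (they
capture the end-points of the network inside the region, analogously to
leaves).  Fluxes are then distributed uniformly within each connected
component so that every component is closed (Σ f_i = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import ContestedTerminalWarning, TerminalSelectionError
from .extraction import ExtractedGraph
from .forcing import ForcingSpec

__all__ = [
    "TerminalSet",
    "eligible_nodes",
    "select_terminals",
    "assign_fluxes",
    "build_terminals",
]

DEFAULT_TAU_BC = 0.1


@dataclass
class TerminalSet:
    """Selected terminals with per-component balanced fluxes."""

    sources: set = field(default_factory=set)
    sinks: set = field(default_factory=set)
    flux: dict = field(default_factory=dict)
    components: list = field(default_factory=list)
    inactive_components: list = field(default_factory=list)


def eligible_nodes(graph: ExtractedGraph, spec: ForcingSpec):
    """Nodes lying in the source / sink supports of the forcing spec."""
    pos = graph.positions()
    nodes = list(graph.graph.nodes)
    pts = np.array([pos[n] for n in nodes]) if nodes else np.empty((0, 2))
    el_src: set = set()
    el_snk: set = set()
    for region in spec.regions:
        inside = region.contains(pts) if len(nodes) else np.empty(0, bool)
        hit = {nodes[k] for k in np.flatnonzero(inside)}
        if region.sign > 0:
            el_src |= hit
        else:
            el_snk |= hit
    if not el_src or not el_snk:
        raise TerminalSelectionError(
            "no eligible source node" if not el_src else "no eligible sink node"
        )
    return el_src, el_snk


def _hull_vertices(nodes: list, pos: dict) -> set:
    """Convex-hull vertices of a point set; degenerate sets keep extremes."""
    if len(nodes) <= 2:
        return set(nodes)
    pts = np.array([pos[n] for n in nodes])
    try:
        hull = ConvexHull(pts)
        return {nodes[k] for k in hull.vertices}
    except QhullError:
        # collinear: keep the two extreme points along the spread direction
        d = pts - pts.mean(axis=0)
        axis = d[np.argmax(np.einsum("id,id->i", d, d))]
        if not np.any(axis):
            return {nodes[0]}
        proj = d @ axis
        return {nodes[int(np.argmin(proj))], nodes[int(np.argmax(proj))]}


def select_terminals(
    graph: ExtractedGraph,
    eligible_sources: set,
    eligible_sinks: set,
    tau_bc: float = DEFAULT_TAU_BC,
) -> TerminalSet:
    """Keep hull vertices and low-betweenness nodes among the eligible ones.

    Betweenness is the normalised unweighted shortest-path betweenness on
    the whole pre-extracted graph.  Nodes eligible for both signs are
    assigned to neither (with a warning).
    """
    contested = eligible_sources & eligible_sinks
    if contested:
        warnings.warn(
            f"{len(contested)} node(s) eligible as both source and sink were dropped",
            ContestedTerminalWarning,
            stacklevel=2,
        )
        eligible_sources = eligible_sources - contested
        eligible_sinks = eligible_sinks - contested
    pos = graph.positions()
    bc = nx.betweenness_centrality(graph.graph, normalized=True)

    def pick(eligible: set, label: str) -> set:
        nodes = sorted(eligible)
        hull = _hull_vertices(nodes, pos)
        chosen = {n for n in nodes if n in hull or bc[n] < tau_bc}
        if not chosen:
            warnings.warn(
                f"no representative {label} survived selection; "
                "falling back to all eligible nodes",
                stacklevel=3,
            )
            chosen = set(nodes)
        return chosen

    sources = pick(eligible_sources, "source")
    sinks = pick(eligible_sinks, "sink")
    return TerminalSet(sources=sources, sinks=sinks)


def assign_fluxes(graph: ExtractedGraph, s_plus: set, s_minus: set) -> TerminalSet:
    """Uniform per-component flux: f_i = ±1/|S^± ∩ C_m|, 0 elsewhere.

    Components lacking a source or a sink are flagged inactive and get
    all-zero flux.
    """
    flux = {n: 0.0 for n in graph.graph.nodes}
    components = [set(c) for c in nx.connected_components(graph.graph)]
    inactive = []
    for m, comp in enumerate(components):
        srcs = sorted(s_plus & comp)
        snks = sorted(s_minus & comp)
        if not srcs or not snks:
            inactive.append(m)
            continue
        for n in srcs:
            flux[n] = 1.0 / len(srcs)
        for n in snks:
            flux[n] = -1.0 / len(snks)
    return TerminalSet(
        sources=set(s_plus),
        sinks=set(s_minus),
        flux=flux,
        components=components,
        inactive_components=inactive,
    )


def build_terminals(
    graph: ExtractedGraph, spec: ForcingSpec, tau_bc: float = DEFAULT_TAU_BC
) -> TerminalSet:
    """Eligibility → representative selection → flux assignment."""
    el_src, el_snk = eligible_nodes(graph, spec)
    sel = select_terminals(graph, el_src, el_snk, tau_bc)
    return assign_fluxes(graph, sel.sources, sel.sinks)
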