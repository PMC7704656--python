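"""Graph pre-extraction: thresholded triangle fields → spatial graphs.

Triangles whose conductivity is at least δ are kept; nodes and edges are
then built by one of three rules:

* **I** (edge-or-node sharing): one node per kept triangle at its
  barycenter; an edge joins triangles sharing a grid edge *or* a grid
  vertex.
* **II** (edge-only sharing): as I, but only full-edge neighbours are
  connected (each node then has degree ≤ 3).
* **III** (original triangulation): the grid vertices and grid edges of
  the kept triangles are used directly.

Edge weights come from the per-triangle density μ: AVG is the arithmetic
mean of the endpoint densities, ER ("effective reweighing") divides each
triangle's density by its node degree, w_ij = μ_i/d_i + μ_j/d_j, which
conserves the total density: Σ_e w_e = Σ_{d_i>0} μ_i.  Rule III always
uses AVG (the mean over the kept triangles adjacent to the grid edge).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import EmptyGraphWarning, InvalidParameterError
from .mesh import TriangularMesh

__all__ = ["ExtractedGraph", "ExtractionConfig", "select_triangles", "pre_extract"]


@dataclass
class ExtractedGraph:
    """Spatial weighted undirected graph.

    ``graph`` is a :class:`networkx.Graph` whose nodes carry a ``pos``
    attribute (2-tuple in Ω) and whose edges carry ``weight`` and
    ``length``.  ``node_source_map`` records, per node, the triangle(s)
    of the mesh it originates from (one for rules I–II, several for the
    grid vertices of rule III, empty for image pixels).
    """

    graph: nx.Graph
    node_source_map: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def positions(self) -> dict:
        return nx.get_node_attributes(self.graph, "pos")

    def weights(self) -> dict:
        return nx.get_edge_attributes(self.graph, "weight")

    def lengths(self) -> dict:
        return nx.get_edge_attributes(self.graph, "length")

    def total_weight(self) -> float:
        # compensated summation keeps the ER conservation identity exact
        return math.fsum(self.weights().values())

    def copy(self) -> "ExtractedGraph":
        return ExtractedGraph(self.graph.copy(), dict(self.node_source_map))


@dataclass
class ExtractionConfig:
    rule: str = "I"
    weight_rule: str = "ER"
    delta: float = 0.01
    length_mode: str = "euclidean"   # or "unit"

    def __post_init__(self) -> None:
        if self.rule not in ("I", "II", "III"):
            raise InvalidParameterError(f"unknown extraction rule {self.rule!r}")
        if self.weight_rule not in ("AVG", "ER"):
            raise InvalidParameterError(f"unknown weight rule {self.weight_rule!r}")
        if self.delta < 0:
            raise InvalidParameterError("delta must be >= 0")
        if self.rule == "III" and self.weight_rule == "ER":
            raise InvalidParameterError(
                "the ER rule does not apply to rule III (use AVG)"
            )
        if self.length_mode not in ("euclidean", "unit"):
            raise InvalidParameterError(f"unknown length mode {self.length_mode!r}")


def _mu_of(solution) -> np.ndarray:
    return np.asarray(getattr(solution, "mu", solution), dtype=float)


def select_triangles(solution, delta: float) -> np.ndarray:
    """Indices of triangles whose tracked density is ≥ delta."""
    if delta < 0:
        raise InvalidParameterError("delta must be >= 0")
    mu = _mu_of(solution)
    sel = np.flatnonzero(mu >= delta)
    if sel.size == 0:
        warnings.warn(
            f"no triangle has density >= {delta}; extraction yields an empty graph",
            EmptyGraphWarning,
            stacklevel=2,
        )
    return sel


def _assign_weights(g: nx.Graph, density: dict, weight_rule: str) -> None:
    if weight_rule == "AVG":
        for i, j in g.edges:
            g.edges[i, j]["weight"] = 0.5 * (density[i] + density[j])
    else:  # ER — degree-normalised, conserves total density
        deg = dict(g.degree)
        for i, j in g.edges:
            g.edges[i, j]["weight"] = density[i] / deg[i] + density[j] / deg[j]


def _assign_lengths(g: nx.Graph, mode: str) -> None:
    if mode == "unit":
        nx.set_edge_attributes(g, 1.0, "length")
    else:
        pos = nx.get_node_attributes(g, "pos")
        for i, j in g.edges:
            pi, pj = np.asarray(pos[i]), np.asarray(pos[j])
            g.edges[i, j]["length"] = float(np.linalg.norm(pi - pj))


def pre_extract(
    mesh: TriangularMesh, solution, config: ExtractionConfig
) -> ExtractedGraph:
    """Build the pre-extracted graph from a per-triangle density field."""
    mu = _mu_of(solution)
    sel = select_triangles(mu, config.delta)
    g = nx.Graph()
    source_map: dict = {}

    if config.rule in ("I", "II"):
        adj = (
            mesh.node_adjacency if config.rule == "I" else mesh.edge_adjacency
        )
        selected = set(int(t) for t in sel)
        for t in sel:
            t = int(t)
            g.add_node(t, pos=tuple(mesh.barycenters[t]))
            source_map[t] = (t,)
        for t in sel:
            for s in adj[int(t)]:
                if s in selected and int(t) < s:
                    g.add_edge(int(t), s)
        density = {t: mu[t] for t in g.nodes}
        _assign_weights(g, density, config.weight_rule)
    else:  # rule III: grid vertices and grid edges of the kept triangles
        selected = set(int(t) for t in sel)
        for t in sel:
            for v in mesh.triangles[int(t)]:
                v = int(v)
                if v not in g:
                    g.add_node(v, pos=tuple(mesh.vertices[v]))
                    source_map[v] = ()
                source_map[v] = tuple(sorted(set(source_map[v]) | {int(t)}))
        edge_tris = mesh.edge_triangles()
        for t in sel:
            a, b, c = (int(v) for v in mesh.triangles[int(t)])
            for u, v in ((a, b), (b, c), (c, a)):
                key = (u, v) if u < v else (v, u)
                if key not in g.edges:
                    kept = [s for s in edge_tris[key] if s in selected]
                    w = float(np.mean([mu[s] for s in kept]))
                    g.add_edge(*key, weight=w)

    _assign_lengths(g, config.length_mode)
    return ExtractedGraph(g, source_map)
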