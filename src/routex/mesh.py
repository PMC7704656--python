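"""Structured triangulations of the unit square.

The spatial discretisation is a conforming triangular mesh of
``Ω = [0, 1]²`` built from an ``ndiv × ndiv`` grid of square cells, each
split into two triangles along its lower-left → upper-right diagonal, then
uniformly refined ``nref`` times by midpoint quadrisection (each triangle
replaced by four congruent children).  All piecewise-constant fields (the
transport density in particular) live on triangles and are attributed to
the triangle barycenter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = ["TriangularMesh", "build_structured_mesh"]


@dataclass
class TriangularMesh:
    """A conforming triangulation of the unit square.

    Attributes
    ----------
    vertices : (n, 2) float array
        Vertex coordinates in Ω = [0, 1]².
    triangles : (m, 3) int array
        Vertex-index triples, counter-clockwise.
    barycenters : (m, 2) float array
        Triangle centroids (mean of the three vertices).
    areas : (m,) float array
        Positive triangle areas; they sum to |Ω| = 1.
    edge_adjacency : list of lists
        For each triangle, indices of triangles sharing a full edge (≤ 3).
    node_adjacency : list of lists
        For each triangle, indices of triangles sharing at least one vertex.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    barycenters: np.ndarray = field(init=False)
    areas: np.ndarray = field(init=False)
    edge_adjacency: list = field(init=False)
    node_adjacency: list = field(init=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        pts = self.vertices[self.triangles]  # (m, 3, 2)
        self.barycenters = pts.mean(axis=1)
        d1 = pts[:, 1] - pts[:, 0]
        d2 = pts[:, 2] - pts[:, 0]
        self.areas = 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
        self._build_adjacency()

    # -- adjacency -----------------------------------------------------
    def _build_adjacency(self) -> None:
        m = len(self.triangles)
        edge_map: dict[tuple[int, int], list[int]] = {}
        for t, (a, b, c) in enumerate(self.triangles):
            for u, v in ((a, b), (b, c), (c, a)):
                key = (int(u), int(v)) if u < v else (int(v), int(u))
                edge_map.setdefault(key, []).append(t)
        self._edge_triangles = edge_map
        self.edge_adjacency = [[] for _ in range(m)]
        for tris in edge_map.values():
            if len(tris) == 2:
                i, j = tris
                self.edge_adjacency[i].append(j)
                self.edge_adjacency[j].append(i)
        vertex_tris: dict[int, list[int]] = {}
        for t, tri in enumerate(self.triangles):
            for v in tri:
                vertex_tris.setdefault(int(v), []).append(t)
        self._vertex_triangles = vertex_tris
        self.node_adjacency = []
        for t, tri in enumerate(self.triangles):
            neigh: set[int] = set()
            for v in tri:
                neigh.update(vertex_tris[int(v)])
            neigh.discard(t)
            self.node_adjacency.append(sorted(neigh))

    # -- queries -------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edge_triangles(self) -> dict[tuple[int, int], list[int]]:
        """Map each grid edge (sorted vertex pair) to its incident triangles."""
        return self._edge_triangles

    def vertex_triangles(self) -> dict[int, list[int]]:
        """Map each grid vertex to the triangles containing it."""
        return self._vertex_triangles


def build_structured_mesh(ndiv: int, nref: int = 0) -> TriangularMesh:
    """Triangulate [0, 1]² with ``2·ndiv²·4^nref`` triangles.

    ``ndiv`` is the number of divisions along each axis; each square cell
    is split into two triangles along the lower-left → upper-right
    diagonal.  ``nref`` uniform refinement sweeps then split every
    triangle into four congruent triangles through the edge midpoints,
    so the vertex set of one level is contained in the next.
    """
    if not (isinstance(ndiv, (int, np.integer)) and ndiv >= 1):
        raise InvalidParameterError(f"ndiv must be a positive integer, got {ndiv!r}")
    if not (isinstance(nref, (int, np.integer)) and nref >= 0):
        raise InvalidParameterError(f"nref must be a non-negative integer, got {nref!r}")

    n = int(ndiv)
    xs = np.linspace(0.0, 1.0, n + 1)
    xv, yv = np.meshgrid(xs, xs, indexing="xy")
    vertices = np.column_stack([xv.ravel(), yv.ravel()])

    def vid(i: int, j: int) -> int:
        return j * (n + 1) + i

    tris = []
    for j in range(n):
        for i in range(n):
            ll, lr = vid(i, j), vid(i + 1, j)
            ul, ur = vid(i, j + 1), vid(i + 1, j + 1)
            tris.append((ll, lr, ur))
            tris.append((ll, ur, ul))
    triangles = np.array(tris, dtype=np.int64)

    verts = [tuple(p) for p in vertices]
    for _ in range(int(nref)):
        verts, triangles = _refine_once(verts, triangles)
    return TriangularMesh(np.array(verts, dtype=float), triangles)


def _refine_once(verts: list, triangles: np.ndarray):
    """Quadrisect every triangle through its edge midpoints (conforming)."""
    midpoint: dict[tuple[int, int], int] = {}
    verts = list(verts)

    def mid(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        idx = midpoint.get(key)
        if idx is None:
            pa, pb = verts[a], verts[b]
            verts.append(((pa[0] + pb[0]) / 2.0, (pa[1] + pb[1]) / 2.0))
            idx = len(verts) - 1
            midpoint[key] = idx
        return idx

    new_tris = []
    for a, b, c in triangles:
        a, b, c = int(a), int(b), int(c)
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_tris.extend([(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)])
    return verts, np.array(new_tris, dtype=np.int64)
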