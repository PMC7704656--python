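"""Evaluation metrics for extracted networks.

Two complementary quantities measure how well a graph compresses the raw
per-triangle density field:

* the local-weight discrepancy ŵ_q — the domain is partitioned into
  P = (N−1)² axis-aligned cells C_α; in each cell the sum of graph edge
  weights (edges straddling a cell boundary count half per side) is
  compared with the raw density mass w_α of the kept triangles, and the
  per-cell gaps are combined as (1/P)[Σ_α |·|^q]^{1/q};
* the total network length L(G) = Σ_e ℓ_e (unit or Euclidean), a proxy
  for how parsimonious the representation is.

The module also provides the vein-length analysis used for biological
networks: maximal chains of degree-2 nodes are contracted into single
junction-to-junction veins and the resulting length distribution is
fitted with an exponential P(ℓ) = P₀ e^{−γℓ}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InvalidParameterError
from .extraction import ExtractedGraph

__all__ = [
    "DomainPartition",
    "MetricReport",
    "local_weight_metric",
    "total_length",
    "edge_length_distribution",
    "fit_exponential",
]


@dataclass
class DomainPartition:
    """P = (N−1)² rectangular cells from N-regular axis partitions of [0,1].

    Cells are half-open ([x_i, x_{i+1}) × [y_j, y_{j+1})) except along the
    top/right boundary, so every point of Ω lands in exactly one cell.
    """

    n: int
    breaks: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidParameterError("partition N must be >= 2")
        self.breaks = np.linspace(0.0, 1.0, self.n)

    @property
    def n_cells(self) -> int:
        return (self.n - 1) ** 2

    def cell_index(self, points: np.ndarray) -> np.ndarray:
        """Flat cell index of each point (last cells closed)."""
        p = np.atleast_2d(points)
        ncell = self.n - 1
        ix = np.clip(np.searchsorted(self.breaks, p[:, 0], side="right") - 1, 0, ncell - 1)
        iy = np.clip(np.searchsorted(self.breaks, p[:, 1], side="right") - 1, 0, ncell - 1)
        return iy * ncell + ix


@dataclass
class MetricReport:
    w_hat: float
    q: float
    L: float
    L_relative: float | None
    per_cell: np.ndarray     # columns: graph-side sum, raw w_α


def local_weight_metric(
    graph: ExtractedGraph,
    mesh,
    mu: np.ndarray,
    delta: float,
    partition: DomainPartition,
    q: float = 2.0,
    L_max: float | None = None,
) -> MetricReport:
    """Compute ŵ_q(G) against the thresholded raw field (μ ≥ δ).

    An edge contributes its full weight to the cell containing both
    endpoints, and half a weight to each of the two cells when its
    endpoints fall in different cells.
    """
    if q < 1:
        raise InvalidParameterError("exponent q must be >= 1")
    mu = np.asarray(getattr(mu, "mu", mu), dtype=float)
    P = partition.n_cells
    raw = np.zeros(P)
    kept = mu >= delta
    if kept.any():
        cells = partition.cell_index(mesh.barycenters[kept])
        np.add.at(raw, cells, mu[kept])
    side = np.zeros(P)
    pos = graph.positions()
    for (i, j), w in graph.weights().items():
        ci = partition.cell_index(np.asarray(pos[i])[None, :])[0]
        cj = partition.cell_index(np.asarray(pos[j])[None, :])[0]
        if ci == cj:
            side[ci] += w
        else:
            side[ci] += 0.5 * w
            side[cj] += 0.5 * w
    w_hat = float((np.sum(np.abs(side - raw) ** q)) ** (1.0 / q) / P)
    L = total_length(graph, "euclidean")
    return MetricReport(
        w_hat=w_hat,
        q=q,
        L=L,
        L_relative=(L / L_max) if L_max else None,
        per_cell=np.column_stack([side, raw]),
    )


def total_length(graph: ExtractedGraph, mode: str = "euclidean") -> float:
    """Total network length: |E| in unit mode, Σ endpoint distances otherwise."""
    if mode == "unit":
        return float(graph.n_edges)
    if mode != "euclidean":
        raise InvalidParameterError(f"unknown length mode {mode!r}")
    pos = graph.positions()
    total = 0.0
    for i, j in graph.graph.edges:
        total += float(np.linalg.norm(np.asarray(pos[i]) - np.asarray(pos[j])))
    return total


def edge_length_distribution(graph: ExtractedGraph) -> list[float]:
    """Vein lengths after contracting maximal chains of degree-2 nodes.

    Every junction-to-junction or junction-to-leaf path whose interior
    nodes all have degree 2 becomes a single vein whose length is the sum
    of its segment (Euclidean) lengths; cycles made entirely of degree-2
    nodes yield one closed vein of the full perimeter.
    """
    g = graph.graph
    lengths = nx.get_edge_attributes(g, "length")

    def seg(u, v):
        return lengths.get((u, v), lengths.get((v, u)))

    veins: list[float] = []
    visited_edges: set = set()
    junctions = [n for n in g.nodes if g.degree(n) != 2]
    for j in junctions:
        for nb in g.neighbors(j):
            key = frozenset((j, nb))
            if key in visited_edges:
                continue
            total = seg(j, nb)
            visited_edges.add(key)
            prev, cur = j, nb
            while g.degree(cur) == 2 and cur != j:
                nxt = next(n for n in g.neighbors(cur) if n != prev)
                visited_edges.add(frozenset((cur, nxt)))
                total += seg(cur, nxt)
                prev, cur = cur, nxt
            veins.append(float(total))
    # pure cycles of degree-2 nodes (no junction on them)
    for u, v in g.edges:
        key = frozenset((u, v))
        if key in visited_edges:
            continue
        total = seg(u, v)
        visited_edges.add(key)
        prev, cur = u, v
        while cur != u:
            nxt = next(n for n in g.neighbors(cur) if n != prev)
            visited_edges.add(frozenset((cur, nxt)))
            total += seg(cur, nxt)
            prev, cur = cur, nxt
        veins.append(float(total))
    return veins


def fit_exponential(
    lengths, bins: int = 30
) -> tuple[float, float, float]:
    """Fit counts of a length histogram with P(ℓ) = P₀ e^{−γℓ}.

    Builds an equal-width count histogram and fits by nonlinear least
    squares on (bin centre, count).  Returns (P₀, γ, residual) where the
    residual is the root-mean-square misfit of the counts.
    """
    lengths = np.asarray(list(lengths), dtype=float)
    if len(lengths) < 10:
        raise InvalidParameterError("need at least 10 lengths to fit")
    if np.ptp(lengths) == 0:
        raise FitFailureError("all lengths identical; exponential fit is degenerate")
    counts, edges = np.histogram(lengths, bins=bins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    mean = lengths.mean()
    p0 = (float(counts.max()), 1.0 / mean if mean > 0 else 1.0)
    try:
        popt, _ = curve_fit(
            lambda x, a, g: a * np.exp(-g * x),
            centres,
            counts,
            p0=p0,
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"exponential fit did not converge: {exc}") from exc
    fitted = popt[0] * np.exp(-popt[1] * centres)
    residual = float(np.sqrt(np.mean((fitted - counts) ** 2)))
    return float(popt[0]), float(popt[1]), residual
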