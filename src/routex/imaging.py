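"""Network extraction from raster images.

A greyscale (or colour) image is turned into an artificial conductivity
field: pixel intensity, block-averaged by a downsampling factor and
mapped to [0, 1], plays the role of the per-triangle density, with pixel
cells taking the place of triangles.  Masked pixels (intensity ≥ δ_img)
become graph nodes at their centres; 4-connectivity corresponds to the
edge-only pre-extraction rule and 8-connectivity to edge-or-node
sharing.  Because the principled filter drives the kept edges towards
trees, loops present in the image are recovered a posteriori: the filter
is fed a maximum-weight spanning forest of the pre-extracted graph, and
afterwards pairs of terminals/leaves of the filtered graph that were
within a small hop radius in the pre-extracted graph — but are farther
apart (or disconnected) after filtering — get their original shortest
path re-inserted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import imageio.v3 as iio
import networkx as nx
import numpy as np
from skimage.color import rgb2gray
from skimage.measure import block_reduce

from .errors import EmptyGraphWarning, InvalidParameterError
from .extraction import ExtractedGraph

__all__ = [
    "DensityGrid",
    "image_to_density",
    "grid_to_pregraph",
    "spanning_forest",
    "recover_loops",
]


@dataclass
class DensityGrid:
    """Downsampled intensity field on a pixel grid mapped into [0, 1]²."""

    values: np.ndarray               # (H, W), in [0, 1]
    threshold: float
    mask: np.ndarray = field(init=False)
    cell_centres: np.ndarray = field(init=False)   # (H, W, 2), x–y coords

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise InvalidParameterError("intensities must be non-negative")
        self.mask = self.values >= self.threshold
        h, w = self.values.shape
        scale = max(h, w)            # longest side maps to 1, aspect preserved
        cols = (np.arange(w) + 0.5) / scale
        rows = (np.arange(h) + 0.5) / scale
        x, yrow = np.meshgrid(cols, rows)
        y = (h / scale) - yrow       # image row 0 is the top of the domain
        self.cell_centres = np.stack([x, y], axis=-1)


def image_to_density(
    image,
    downsample: int = 1,
    mapping: str = "greyscale",
    threshold: float = 0.0,
) -> DensityGrid:
    """Read a raster image and map its intensity to a density grid.

    ``image`` is a path or an array.  ``mapping`` is ``"greyscale"``
    (luminance) or one of ``"red"/"green"/"blue"`` to use a single
    channel.  Downsampling is by block mean over ``downsample``-sized
    blocks; pixels below ``threshold`` are masked out.
    """
    if downsample < 1:
        raise InvalidParameterError("downsample factor must be >= 1")
    arr = iio.imread(image) if not isinstance(image, np.ndarray) else image
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.ndim == 3:
        if mapping == "greyscale":
            arr = rgb2gray(arr[..., :3])
        elif mapping in ("red", "green", "blue"):
            arr = arr[..., ("red", "green", "blue").index(mapping)]
        else:
            raise InvalidParameterError(f"unknown intensity mapping {mapping!r}")
    elif mapping != "greyscale" and arr.ndim == 2:
        pass  # single-channel image: any mapping reads the sole channel
    if downsample > 1:
        arr = block_reduce(arr, (downsample, downsample), np.mean)
    grid = DensityGrid(np.clip(arr, 0.0, 1.0), threshold)
    if not grid.mask.any():
        warnings.warn(
            "no pixel reaches the intensity threshold; the graph will be empty",
            EmptyGraphWarning,
            stacklevel=2,
        )
    return grid


_OFFSETS_4 = [(0, 1), (1, 0)]
_OFFSETS_8 = [(0, 1), (1, 0), (1, 1), (1, -1)]


def grid_to_pregraph(
    grid: DensityGrid, connectivity: int = 8, weight_rule: str = "AVG"
) -> ExtractedGraph:
    """Pre-extract a graph from the masked pixels of a density grid."""
    if connectivity not in (4, 8):
        raise InvalidParameterError("connectivity must be 4 or 8")
    if weight_rule not in ("AVG", "ER"):
        raise InvalidParameterError(f"unknown weight rule {weight_rule!r}")
    h, w = grid.values.shape
    g = nx.Graph()
    idx = {}
    for r, c in zip(*np.nonzero(grid.mask)):
        n = int(r) * w + int(c)
        idx[(int(r), int(c))] = n
        g.add_node(n, pos=tuple(grid.cell_centres[r, c]))
    offsets = _OFFSETS_4 if connectivity == 4 else _OFFSETS_8
    for (r, c), n in idx.items():
        for dr, dc in offsets:
            m = idx.get((r + dr, c + dc))
            if m is not None:
                g.add_edge(n, m)
    density = {idx[(r, c)]: grid.values[r, c] for (r, c) in idx}
    if weight_rule == "AVG":
        for i, j in g.edges:
            g.edges[i, j]["weight"] = 0.5 * (density[i] + density[j])
    else:
        deg = dict(g.degree)
        for i, j in g.edges:
            g.edges[i, j]["weight"] = density[i] / deg[i] + density[j] / deg[j]
    pos = nx.get_node_attributes(g, "pos")
    for i, j in g.edges:
        g.edges[i, j]["length"] = float(
            np.linalg.norm(np.asarray(pos[i]) - np.asarray(pos[j]))
        )
    return ExtractedGraph(g, {n: () for n in g.nodes})


def spanning_forest(pregraph: ExtractedGraph) -> ExtractedGraph:
    """Maximum-weight spanning forest — the tree-like filter input."""
    forest = nx.maximum_spanning_tree(pregraph.graph, weight="weight")
    for n in forest.nodes:
        forest.nodes[n]["pos"] = pregraph.graph.nodes[n]["pos"]
    return ExtractedGraph(
        forest, {n: pregraph.node_source_map.get(n, ()) for n in forest.nodes}
    )


def recover_loops(
    pregraph: ExtractedGraph,
    filtered: ExtractedGraph,
    terminals=None,
    radius: int = 2,
) -> ExtractedGraph:
    """Re-insert short pre-extraction paths between nearby end nodes.

    Candidate nodes are the terminals (if given) plus the leaves of the
    filtered graph.  For every candidate pair at hop distance ≤ radius in
    the pre-extracted graph whose distance in the filtered graph is
    larger (or infinite), the pre-extracted shortest path is added back,
    restoring loops removed by the tree-producing filter.  ``radius=0``
    returns the filtered graph unchanged.
    """
    out = filtered.copy()
    if radius <= 0:
        return out
    g_pre = pregraph.graph
    candidates = sorted(
        n
        for n in out.graph.nodes
        if out.graph.degree(n) <= 1
        or (terminals is not None and (n in terminals.sources or n in terminals.sinks))
    )
    for a in candidates:
        if a not in g_pre:
            continue
        near = nx.single_source_shortest_path(g_pre, a, cutoff=radius)
        for b, path in near.items():
            if b <= a or b not in out.graph.nodes or b not in set(candidates):
                continue
            d_pre = len(path) - 1
            try:
                d_filt = nx.shortest_path_length(out.graph, a, b)
            except nx.NetworkXNoPath:
                d_filt = np.inf
            if d_filt > d_pre:
                for u, v in zip(path[:-1], path[1:]):
                    out.graph.add_edge(u, v, **g_pre.edges[u, v])
                    for n in (u, v):
                        out.graph.nodes[n]["pos"] = g_pre.nodes[n]["pos"]
                        out.node_source_map.setdefault(
                            n, pregraph.node_source_map.get(n, ())
                        )
    return out
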