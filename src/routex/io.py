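"""Readers and writers for meshes, solutions, graphs and reports.

Graphs travel either as GraphML (positions flattened to ``x``/``y`` node
attributes) or as a TSV pair: an edge list (u, v, weight, length) and a
node table (id, x, y).  Meshes use a small self-describing text format
(vertex table + 0-based triangle index table).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .extraction import ExtractedGraph
from .mesh import TriangularMesh

__all__ = [
    "write_mesh",
    "read_mesh",
    "write_graph_tsv",
    "read_graph_tsv",
    "write_graphml",
    "read_graphml",
    "write_solution",
    "write_energy_trace",
    "write_terminal_report",
    "write_json",
]


# -- mesh ------------------------------------------------------------------
def write_mesh(mesh: TriangularMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("# routex mesh: vertex table then triangle table, 0-based indices\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_triangles}\n")
        for x, y in mesh.vertices:
            fh.write(f"{float(x)!r} {float(y)!r}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"{a} {b} {c}\n")


def read_mesh(path) -> TriangularMesh:
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    nv, nt = (int(t) for t in lines[0].split())
    verts = np.array([[float(t) for t in ln.split()] for ln in lines[1 : 1 + nv]])
    tris = np.array(
        [[int(t) for t in ln.split()] for ln in lines[1 + nv : 1 + nv + nt]]
    )
    return TriangularMesh(verts, tris)


# -- graphs ----------------------------------------------------------------
def write_graph_tsv(graph: ExtractedGraph, edge_path, node_path) -> None:
    pos = graph.positions()
    edges = sorted(tuple(sorted(e)) for e in graph.graph.edges)
    rows = [
        {
            "u": u,
            "v": v,
            "weight": graph.graph.edges[u, v]["weight"],
            "length": graph.graph.edges[u, v]["length"],
        }
        for u, v in edges
    ]
    pd.DataFrame(rows, columns=["u", "v", "weight", "length"]).to_csv(
        edge_path, sep="\t", index=False
    )
    nrows = [{"id": n, "x": pos[n][0], "y": pos[n][1]} for n in sorted(graph.graph.nodes)]
    pd.DataFrame(nrows, columns=["id", "x", "y"]).to_csv(
        node_path, sep="\t", index=False
    )


def read_graph_tsv(edge_path, node_path) -> ExtractedGraph:
    g = nx.Graph()
    nodes = pd.read_csv(node_path, sep="\t")
    for _, row in nodes.iterrows():
        g.add_node(int(row["id"]), pos=(float(row["x"]), float(row["y"])))
    edges = pd.read_csv(edge_path, sep="\t")
    for _, row in edges.iterrows():
        g.add_edge(
            int(row["u"]),
            int(row["v"]),
            weight=float(row["weight"]),
            length=float(row["length"]),
        )
    return ExtractedGraph(g, {n: () for n in g.nodes})


def write_graphml(graph: ExtractedGraph, path) -> None:
    g = nx.Graph()
    for n, p in graph.positions().items():
        g.add_node(n, x=float(p[0]), y=float(p[1]))
    for (u, v), w in graph.weights().items():
        g.add_edge(u, v, weight=float(w), length=float(graph.graph.edges[u, v]["length"]))
    nx.write_graphml(g, path)


def read_graphml(path) -> ExtractedGraph:
    raw = nx.read_graphml(path)
    g = nx.Graph()
    for n, data in raw.nodes(data=True):
        g.add_node(int(n), pos=(float(data["x"]), float(data["y"])))
    for u, v, data in raw.edges(data=True):
        g.add_edge(
            int(u), int(v),
            weight=float(data["weight"]),
            length=float(data["length"]),
        )
    return ExtractedGraph(g, {n: () for n in g.nodes})


# -- solutions and reports -------------------------------------------------
def write_solution(mesh: TriangularMesh, solution, tri_path, vertex_path) -> None:
    """Per-triangle (id, x, y, mu, |grad u|) and per-vertex (id, x, y, u) TSVs."""
    tri = pd.DataFrame(
        {
            "triangle": np.arange(mesh.n_triangles),
            "x": mesh.barycenters[:, 0],
            "y": mesh.barycenters[:, 1],
            "mu": solution.mu,
            "grad_norm": solution.grad_norm,
        }
    )
    tri.to_csv(tri_path, sep="\t", index=False)
    vert = pd.DataFrame(
        {
            "vertex": np.arange(mesh.n_vertices),
            "x": mesh.vertices[:, 0],
            "y": mesh.vertices[:, 1],
            "u": solution.u,
        }
    )
    vert.to_csv(vertex_path, sep="\t", index=False)


def write_energy_trace(trace, path) -> None:
    pd.DataFrame({"iteration": np.arange(len(trace)), "energy": trace}).to_csv(
        path, index=False
    )


def write_terminal_report(graph: ExtractedGraph, terminals, path) -> None:
    pos = graph.positions()
    comp_of = {}
    for m, comp in enumerate(terminals.components):
        for n in comp:
            comp_of[n] = m
    rows = []
    for n in sorted(graph.graph.nodes):
        role = (
            "source" if n in terminals.sources
            else "sink" if n in terminals.sinks
            else "none"
        )
        rows.append(
            {
                "id": n,
                "x": pos[n][0],
                "y": pos[n][1],
                "role": role,
                "flux": terminals.flux.get(n, 0.0),
                "component": comp_of.get(n, -1),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
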