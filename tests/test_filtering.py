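"""Discrete dynamics filter: fixed points, energy, pruning, LP oracle."""

import networkx as nx
import numpy as np
import pytest
from scipy.optimize import linprog

from routex import (
    DiscreteProblem,
    ExtractedGraph,
    discrete_energy,
    prune_and_reweight,
    run_discrete_dmk,
)
from routex.errors import InvalidParameterError, UnbalancedForcingError


def lp_min_cost_flux(n, edges, lengths, f):
    """Independent min-cost-flow oracle: min Σ ℓ_e|q_e| s.t. B q = f."""
    B = np.zeros((n, len(edges)))
    for e, (u, v) in enumerate(edges):
        B[u, e] = 1.0
        B[v, e] = -1.0
    c = np.concatenate([lengths, lengths])
    r = linprog(c, A_eq=np.hstack([B, -B]), b_eq=f, bounds=(0, None), method="highs")
    assert r.status == 0
    return np.abs(r.x[: len(edges)] - r.x[len(edges):])


def _graph_with(edges, weights, lengths, pos=None):
    g = nx.Graph()
    for (u, v), w, l in zip(edges, weights, lengths):
        g.add_edge(u, v, weight=w, length=l)
    pos = pos or {}
    for n in g.nodes:
        g.nodes[n]["pos"] = pos.get(n, (0.0, 0.0))
    return ExtractedGraph(g, {})


def test_single_edge_fixed_point():
    """Kirchhoff forces |q|=1, so μ* = 1 for any β_d, ℓ, μ0."""
    for beta_d, ell, mu0 in [(1.0, 1.0, 0.3), (1.3, 2.5, 4.0), (1.8, 0.2, 1e-2)]:
        p = DiscreteProblem([0, 1], [(0, 1)], [ell], [1.0, -1.0], beta_d, [mu0])
        r = run_discrete_dmk(p, tol=1e-10, max_iter=20000)
        assert r.converged
        assert r.mu_star[0] == pytest.approx(1.0, abs=1e-6)


def test_triangle_equal_lengths_prefers_direct_edge():
    p = DiscreteProblem(
        [0, 1, 2], [(0, 1), (0, 2), (1, 2)], [1.0, 1.0, 1.0],
        [1.0, -1.0, 0.0], 1.0, [1.0, 1.0, 1.0],
    )
    r = run_discrete_dmk(p, tol=1e-9, max_iter=20000)
    assert r.mu_star[0] == pytest.approx(1.0, abs=1e-6)
    assert r.mu_star[1] < 1e-6 and r.mu_star[2] < 1e-6


def test_triangle_routes_around_long_edge():
    """Path 0–2–1 of length 2 beats the direct edge of length 3."""
    p = DiscreteProblem(
        [0, 1, 2], [(0, 1), (0, 2), (1, 2)], [3.0, 1.0, 1.0],
        [1.0, -1.0, 0.0], 1.0, [1.0, 1.0, 1.0],
    )
    r = run_discrete_dmk(p, tol=1e-9, max_iter=20000)
    assert r.mu_star[0] < 1e-6
    assert r.mu_star[1] == pytest.approx(1.0, abs=1e-6)
    assert r.mu_star[2] == pytest.approx(1.0, abs=1e-6)


def test_beta_below_one_rejected():
    with pytest.raises(InvalidParameterError):
        DiscreteProblem([0, 1], [(0, 1)], [1.0], [1.0, -1.0], 0.9, [1.0])


def test_unbalanced_forcing_rejected():
    with pytest.raises(UnbalancedForcingError):
        DiscreteProblem([0, 1], [(0, 1)], [1.0], [1.0, -0.5], 1.0, [1.0])


def test_energy_split_single_edge():
    """At the single-edge equilibrium both cost terms are ½ (50%/50%)."""
    p = DiscreteProblem([0, 1], [(0, 1)], [1.0], [1.0, -1.0], 1.0, [1.0])
    r = run_discrete_dmk(p, tol=1e-10, max_iter=20000)
    total, oper, infra = discrete_energy(p, r.mu_star, r.u_star)
    assert oper == pytest.approx(0.5, abs=1e-6)
    assert infra == pytest.approx(0.5, abs=1e-6)
    assert r.energy_split[0] == pytest.approx(50.0, abs=1e-3)
    assert r.energy_split[1] == pytest.approx(50.0, abs=1e-3)


def test_energy_zero_for_zero_mu():
    p = DiscreteProblem([0, 1], [(0, 1)], [1.0], [1.0, -1.0], 1.0, [1.0])
    total, oper, infra = discrete_energy(p, np.zeros(1), np.zeros(2))
    assert total == oper == infra == 0.0


def test_energy_trace_monotone_on_random_graph(rng):
    g = nx.gnm_random_graph(10, 20, seed=4)
    edges = [tuple(sorted(e)) for e in g.edges]
    lengths = rng.uniform(0.5, 2.0, len(edges))
    f = np.zeros(10)
    f[0], f[9] = 1.0, -1.0
    p = DiscreteProblem(list(range(10)), edges, lengths, f, 1.4, np.ones(len(edges)))
    r = run_discrete_dmk(p)
    assert np.all(np.diff(r.energy_trace) <= 1e-8 * abs(r.energy_trace[0]))


def test_kirchhoff_residual_bounded(rng):
    g = nx.gnm_random_graph(12, 24, seed=5)
    edges = [tuple(sorted(e)) for e in g.edges]
    f = np.zeros(12)
    f[0], f[11] = 1.0, -1.0
    p = DiscreteProblem(
        list(range(12)), edges, rng.uniform(0.5, 2, len(edges)), f, 1.2,
        np.ones(len(edges)),
    )
    r = run_discrete_dmk(p)
    assert r.kirchhoff_residual <= 1e-8


def test_lp_oracle_on_small_graph_sample(rng):
    """β_d=1 equilibrium flux = min-cost flow on random small graphs."""
    for seed in range(8):
        g = nx.gnm_random_graph(6, 9, seed=seed)
        if not nx.is_connected(g):
            continue
        edges = [tuple(sorted(e)) for e in g.edges]
        lengths = rng.uniform(0.5, 2.0, len(edges))
        f = np.zeros(6)
        f[0], f[5] = 1.0, -1.0
        p = DiscreteProblem(list(range(6)), edges, lengths, f, 1.0, np.ones(len(edges)))
        r = run_discrete_dmk(p, dt=0.45, tol=1e-9, max_iter=80000)
        ref = lp_min_cost_flux(6, edges, lengths, f)
        np.testing.assert_allclose(np.abs(r.flux), ref, atol=1e-4)


def test_prune_and_reweight_modes():
    edges = [(0, 1), (1, 2)]
    graph = _graph_with(edges, weights=[0.7, 0.4], lengths=[1.0, 1.0])
    p = DiscreteProblem([0, 1, 2], edges, [1.0, 1.0], [1.0, 0.0, -1.0], 1.0,
                        [0.7, 0.4])
    r = run_discrete_dmk(p, tol=1e-10, max_iter=20000)
    bpw = prune_and_reweight(r, graph, delta_d=1e-3, mode="BPW")
    ibp = prune_and_reweight(r, graph, delta_d=1e-3, mode="IBP")
    # both edges carry unit flux, so both survive; IBP keeps the old weights
    assert bpw.graph.edges[0, 1]["weight"] == pytest.approx(1.0, abs=1e-6)
    assert ibp.graph.edges[0, 1]["weight"] == 0.7
    assert ibp.graph.edges[1, 2]["weight"] == 0.4


def test_prune_threshold_drops_dead_edges():
    """μ* = (1.0, ~0) with δ_d = 10⁻³ keeps only the live edge."""
    edges = [(0, 1), (0, 2), (1, 2)]
    graph = _graph_with(edges, [1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    p = DiscreteProblem([0, 1, 2], edges, [1.0, 1.0, 1.0], [1.0, -1.0, 0.0],
                        1.0, [1.0, 1.0, 1.0])
    r = run_discrete_dmk(p, tol=1e-9, max_iter=20000)
    out = prune_and_reweight(r, graph, delta_d=1e-3, mode="BPW")
    assert set(map(frozenset, out.graph.edges)) == {frozenset((0, 1))}
    assert set(out.graph.nodes) <= set(graph.graph.nodes)


def test_filtered_graph_acyclic_for_branched_beta(rng):
    """β_d>1 with generic lengths yields a forest per active component."""
    g = nx.grid_2d_graph(4, 4)
    g = nx.convert_node_labels_to_integers(g, ordering="sorted")
    edges = [tuple(sorted(e)) for e in g.edges]
    lengths = rng.uniform(0.8, 1.2, len(edges))  # generic: no exact ties
    f = np.zeros(16)
    f[0], f[15] = 1.0, -1.0
    graph = _graph_with(edges, np.ones(len(edges)), lengths)
    p = DiscreteProblem(list(range(16)), edges, lengths, f, 1.3, np.ones(len(edges)))
    r = run_discrete_dmk(p, tol=1e-9, max_iter=40000)
    out = prune_and_reweight(r, graph, delta_d=1e-3, mode="BPW")
    assert nx.is_forest(out.graph)


def test_inactive_component_passthrough_or_drop():
    edges = [(0, 1), (2, 3)]
    graph = _graph_with(edges, [0.5, 0.9], [1.0, 1.0])
    p = DiscreteProblem([0, 1, 2, 3], edges, [1.0, 1.0], [1.0, -1.0, 0.0, 0.0],
                        1.1, [0.5, 0.9])
    r = run_discrete_dmk(p, tol=1e-9, max_iter=20000)
    dropped = prune_and_reweight(r, graph, 1e-3, "BPW", drop_inactive=True)
    kept = prune_and_reweight(r, graph, 1e-3, "BPW", drop_inactive=False)
    assert (2, 3) not in dropped.graph.edges
    assert kept.graph.edges[2, 3]["weight"] == 0.9  # untouched pre-filter weight
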