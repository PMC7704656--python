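"""Continuous solver: elliptic solve, relaxation dynamics, energy."""

import numpy as np
import pytest

from routex import (
    DmkOptions,
    build_structured_mesh,
    cut_flux,
    evaluate_forcing,
    generate_fixture,
    lyapunov_energy,
    run_continuous_dmk,
    solve_potential,
)
from routex.errors import (
    InvalidParameterError,
    InvalidStateError,
    UnbalancedForcingError,
)


def _independent_stiffness(mesh):
    """P1 stiffness assembled from scratch: fit the plane of each basis
    function on every triangle and integrate the constant gradients."""
    n = mesh.n_vertices
    K = np.zeros((n, n))
    for tri, area in zip(mesh.triangles, mesh.areas):
        pts = mesh.vertices[tri]
        V = np.column_stack([np.ones(3), pts])  # plane coefficients a+bx+cy
        grads = []
        for k in range(3):
            e = np.zeros(3)
            e[k] = 1.0
            coef = np.linalg.solve(V, e)
            grads.append(coef[1:])
        for a in range(3):
            for b in range(3):
                K[tri[a], tri[b]] += area * grads[a] @ grads[b]
    return K


def test_potential_matches_hand_assembled_system():
    """Direct dense solve of the independently assembled 4×4 system."""
    mesh = build_structured_mesh(1)
    f = np.array([0.5, -0.5])  # one triangle injects, the other absorbs
    K = _independent_stiffness(mesh)
    b = np.zeros(mesh.n_vertices)
    for t, tri in enumerate(mesh.triangles):
        b[tri] += f[t] / 3.0
    u_ref = np.zeros(mesh.n_vertices)
    u_ref[1:] = np.linalg.solve(K[1:, 1:], b[1:])
    u_ref -= u_ref.mean()
    u = solve_potential(mesh, np.ones(2), f)
    np.testing.assert_allclose(u, u_ref, atol=1e-10)


def test_zero_forcing_gives_zero_potential(mesh8):
    u = solve_potential(mesh8, np.ones(mesh8.n_triangles), np.zeros(mesh8.n_triangles))
    np.testing.assert_allclose(u, 0.0, atol=1e-12)


def test_potential_scales_inversely_with_conductivity(mesh8, two_rect_spec):
    f = evaluate_forcing(mesh8, two_rect_spec)
    u1 = solve_potential(mesh8, np.ones(mesh8.n_triangles), f)
    u2 = solve_potential(mesh8, 2.0 * np.ones(mesh8.n_triangles), f)
    np.testing.assert_allclose(u2, 0.5 * u1, atol=1e-12)


def test_unbalanced_forcing_rejected(mesh8):
    f = np.zeros(mesh8.n_triangles)
    f[0] = 1.0
    with pytest.raises(UnbalancedForcingError):
        solve_potential(mesh8, np.ones(mesh8.n_triangles), f)


def test_nonpositive_conductivity_rejected(mesh8):
    mu = np.ones(mesh8.n_triangles)
    mu[3] = 0.0
    with pytest.raises(InvalidStateError):
        solve_potential(mesh8, mu, np.zeros(mesh8.n_triangles))


# -- energy ----------------------------------------------------------------
def test_energy_by_direct_substitution(mesh8):
    # μ≡1, u≡0, β=1 (P=1): dissipation 0, infrastructure ∫1 dx = 1
    e = lyapunov_energy(
        mesh8, np.ones(mesh8.n_triangles), np.zeros(mesh8.n_vertices), 1.0
    )
    assert e == pytest.approx(1.0, abs=1e-12)
    # β=1.2 → P=2/3: ∫ μ^{2/3}/(2/3) dx = 3/2 for μ≡1
    e = lyapunov_energy(
        mesh8, np.ones(mesh8.n_triangles), np.zeros(mesh8.n_vertices), 1.2
    )
    assert e == pytest.approx(1.5, abs=1e-12)


def test_energy_rejects_beta_two(mesh8):
    with pytest.raises(InvalidParameterError):
        lyapunov_energy(
            mesh8, np.ones(mesh8.n_triangles), np.zeros(mesh8.n_vertices), 2.0
        )


def test_options_validation():
    with pytest.raises(InvalidParameterError):
        DmkOptions(beta=0.8)
    with pytest.raises(InvalidParameterError):
        DmkOptions(beta=2.0)
    with pytest.raises(InvalidParameterError):
        DmkOptions(dt=-0.1)


# -- dynamics --------------------------------------------------------------
def test_energy_trace_monotone_branched(branched16_run):
    _, _, sol = branched16_run
    diffs = np.diff(sol.energy_trace)
    assert np.all(diffs <= 1e-8 * abs(sol.energy_trace[0]))


def test_eikonal_property_at_beta_one(beta1_run):
    """At β=1 equilibrium, |∇u|≈1 wherever the transport density lives."""
    mesh, f, sol = beta1_run
    support = sol.mu >= 0.01 * sol.mu.max()
    assert support.any()
    assert np.max(np.abs(sol.grad_norm[support] - 1.0)) <= 0.05


def test_support_connects_source_to_sink():
    """The high-μ triangles form one edge-connected band between the regions."""
    import collections

    mesh = build_structured_mesh(16)
    spec = generate_fixture("two-rectangles")
    f = evaluate_forcing(mesh, spec)
    sol = run_continuous_dmk(mesh, f, 1.0, DmkOptions(beta=1.05, max_iter=4000))
    support = set(np.flatnonzero(sol.mu >= 0.01 * sol.mu.max()).tolist())
    src = [t for t in support if f.values[t] > 0]
    snk = [t for t in support if f.values[t] < 0]
    assert src and snk
    # breadth-first search over vertex-sharing adjacency restricted to the
    # support: on structured meshes the transport band alternates between the
    # two triangle orientations, so consecutive band triangles share a vertex
    # but not necessarily an edge (the reason extraction rule I exists)
    seen = {src[0]}
    queue = collections.deque(seen)
    while queue:
        t = queue.popleft()
        for s in mesh.node_adjacency[t]:
            if s in support and s not in seen:
                seen.add(s)
                queue.append(s)
    assert support == seen  # single band
    assert any(t in seen for t in snk)


def test_higher_beta_consolidates_support(branched16_run, beta12_16_solution):
    _, _, sol_low = branched16_run
    sol_high = beta12_16_solution
    n_low = np.sum(sol_low.mu >= 0.01 * sol_low.mu.max())
    n_high = np.sum(sol_high.mu >= 0.01 * sol_high.mu.max())
    assert n_high <= n_low


def test_cut_flux_equals_injected_mass(beta1_run):
    """FE flux through any cut isolating the sources equals the source mass."""
    mesh, f, sol = beta1_run
    src_vertices = set(mesh.triangles[f.values > 0].ravel().tolist())
    snk_vertices = set(mesh.triangles[f.values < 0].ravel().tolist())
    assert not src_vertices & snk_vertices
    assert cut_flux(mesh, sol.mu, sol.u, src_vertices) == pytest.approx(1.0, abs=1e-6)
    assert cut_flux(mesh, sol.mu, sol.u, snk_vertices) == pytest.approx(-1.0, abs=1e-6)


def test_mu_stays_nonnegative_and_floor_clipped(branched16_run):
    _, _, sol = branched16_run
    assert np.all(sol.mu >= 1e-10)


@pytest.mark.parametrize("beta", [1.05, 1.1])
def test_equilibrium_energy_stable_under_refinement(beta):
    """Equilibrium energy moves <5% between refinement levels.

    Checked in the mildly branched regime; at strong branching (β ≳ 1.2)
    the equilibrium support is singular and the energy converges only
    slowly in mesh size.
    """
    energies = []
    for nref in (0, 1):
        mesh = build_structured_mesh(12, nref)
        f = evaluate_forcing(mesh, generate_fixture("two-rectangles"))
        sol = run_continuous_dmk(mesh, f, 1.0, DmkOptions(beta=beta, max_iter=12000))
        assert sol.converged
        energies.append(sol.energy_trace[-1])
    assert abs(energies[1] - energies[0]) < 0.05 * abs(energies[0])


def test_nonconvergence_is_flagged_not_raised(mesh8, two_rect_spec):
    f = evaluate_forcing(mesh8, two_rect_spec)
    sol = run_continuous_dmk(mesh8, f, 1.0, DmkOptions(beta=1.1, max_iter=3))
    assert sol.converged is False
    assert sol.iterations == 3
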