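"""Continuous dynamical Monge–Kantorovich solver on a triangulation.

The routing problem couples an elliptic balance law with a relaxation
dynamics for the transport density μ:

    −∇·(μ ∇u) = f,      ∂μ/∂t = (μ |∇u|)^β − μ,      μ(0) = μ0 > 0,

with no-flow Neumann boundary conditions.  The potential ``u`` is
discretised with piecewise-linear (P1) finite elements on the vertices,
μ is piecewise constant on triangles, and the dynamics is integrated by
explicit relaxation with an energy-guarded step size.  At equilibrium the
pair (μ*, u*) minimises the transport functional

    L(μ, u) = ½ ∫ μ |∇u|² dx + ∫ μ^{P(β)} / P(β) dx,   P(β) = (2−β)/β,

whose two terms are the dissipated (operating) energy and the
infrastructure cost.  β = 1 gives shortest-path-like flows (at optimality
|∇u| = 1 on the support of μ*); β > 1 consolidates flow into branched,
network-like structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import (
    InvalidParameterError,
    InvalidStateError,
    NumericalFailureError,
    UnbalancedForcingError,
)
from .forcing import ForcingField
from .mesh import TriangularMesh

__all__ = [
    "DmkOptions",
    "ContinuousSolution",
    "P1Assembler",
    "solve_potential",
    "run_continuous_dmk",
    "lyapunov_energy",
    "cut_flux",
]

_BALANCE_TOL = 1e-10


@dataclass
class DmkOptions:
    """Parameters of the relaxation dynamics.

    beta ∈ [1, 2) selects the routing regime, dt the (initial) step of the
    explicit update, tol the relative-rate stopping threshold on μ,
    delta_floor the positive floor keeping the stiffness matrix
    invertible while μ decays on unused triangles.
    """

    beta: float = 1.1
    dt: float = 0.1
    tol: float = 1e-4
    max_iter: int = 2000
    delta_floor: float = 1e-10

    def __post_init__(self) -> None:
        if not (1.0 <= self.beta < 2.0):
            raise InvalidParameterError(f"beta must lie in [1, 2), got {self.beta}")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.tol <= 0:
            raise InvalidParameterError("tol must be positive")
        if self.delta_floor <= 0:
            raise InvalidParameterError("delta_floor must be positive")


@dataclass
class ContinuousSolution:
    """Equilibrium fields of the continuous dynamics."""

    mu: np.ndarray                 # per-triangle conductivity μ*
    u: np.ndarray                  # per-vertex potential u* (zero mean)
    grad_norm: np.ndarray          # per-triangle |∇u*|
    flux_magnitude: np.ndarray     # per-triangle μ*|∇u*|
    iterations: int
    converged: bool
    energy_trace: np.ndarray       # transport functional per accepted step
    beta: float = 1.1


class P1Assembler:
    """Caches the P1 element data of a mesh for repeated solves.

    The local stiffness of a triangle T with constant conductivity μ_T is
    ``μ_T · |T| · G Gᵀ`` where the rows of G are the (constant) gradients
    of the barycentric basis functions.
    """

    def __init__(self, mesh: TriangularMesh):
        self.mesh = mesh
        pts = mesh.vertices[mesh.triangles]       # (m, 3, 2)
        m = mesh.n_triangles
        # gradients of barycentric coordinates: grad λ_i = rot90(edge opposite i)/(2A)
        e0 = pts[:, 2] - pts[:, 1]
        e1 = pts[:, 0] - pts[:, 2]
        e2 = pts[:, 1] - pts[:, 0]
        # signed double area
        twoA = e2[:, 0] * (-e1[:, 1]) - e2[:, 1] * (-e1[:, 0])
        rot = lambda v: np.column_stack([-v[:, 1], v[:, 0]])
        grads = np.stack([rot(e0), rot(e1), rot(e2)], axis=1) / twoA[:, None, None]
        self.grads = grads                        # (m, 3, 2)
        # local stiffness (without μ): area * G @ G.T  → (m, 3, 3)
        self.k_local = mesh.areas[:, None, None] * np.einsum(
            "tid,tjd->tij", grads, grads
        )
        tri = mesh.triangles
        self._rows = np.repeat(tri, 3, axis=1).ravel()      # i index per entry
        self._cols = np.tile(tri, (1, 3)).ravel()           # j index per entry
        self._k_flat = self.k_local.reshape(m, 9)
        self.n = mesh.n_vertices

    def stiffness(self, mu: np.ndarray) -> sp.csr_matrix:
        data = (self._k_flat * np.asarray(mu)[:, None]).ravel()
        return sp.coo_matrix(
            (data, (self._rows, self._cols)), shape=(self.n, self.n)
        ).tocsr()

    def load(self, f: np.ndarray) -> np.ndarray:
        """Vertex load from per-triangle integrated masses (split evenly)."""
        b = np.zeros(self.n)
        np.add.at(b, self.mesh.triangles.ravel(),
                  np.repeat(np.asarray(f) / 3.0, 3))
        return b

    def gradient(self, u: np.ndarray) -> np.ndarray:
        """Per-triangle constant gradient of a vertex field."""
        uv = np.asarray(u)[self.mesh.triangles]             # (m, 3)
        return np.einsum("ti,tid->td", uv, self.grads)

    def solve(self, mu: np.ndarray, f: np.ndarray) -> np.ndarray:
        """Solve −∇·(μ∇u)=f with natural BCs; zero-mean u returned."""
        mu = np.asarray(mu, dtype=float)
        if np.any(mu <= 0):
            raise InvalidStateError("conductivity must be strictly positive")
        f = np.asarray(f, dtype=float)
        scale = np.abs(f).sum() or 1.0
        if abs(f.sum()) > _BALANCE_TOL * scale:
            raise UnbalancedForcingError(
                f"forcing sums to {f.sum():.3e}; pure Neumann problem is singular"
            )
        A = self.stiffness(mu)
        b = self.load(f)
        # ground vertex 0 to remove the constant nullspace, then re-centre
        free = np.arange(1, self.n)
        u = np.zeros(self.n)
        u[1:] = spla.spsolve(A[free][:, free].tocsc(), b[free])
        u -= u.mean()
        return u


def solve_potential(
    mesh: TriangularMesh, mu: np.ndarray, f: ForcingField | np.ndarray
) -> np.ndarray:
    """P1 solve of the balance law −∇·(μ∇u)=f; returns zero-mean vertex u."""
    values = f.values if isinstance(f, ForcingField) else np.asarray(f)
    return P1Assembler(mesh).solve(mu, values)


def _p_exponent(beta: float) -> float:
    p = (2.0 - beta) / beta
    if p == 0.0:
        raise InvalidParameterError("beta = 2 gives P(beta) = 0 (division by zero)")
    return p


def lyapunov_energy(
    mesh: TriangularMesh,
    mu: np.ndarray,
    u: np.ndarray,
    beta: float,
    *,
    grad: np.ndarray | None = None,
    assembler: P1Assembler | None = None,
) -> float:
    """Transport functional ½∫μ|∇u|² + ∫μ^P/P with P = (2−β)/β."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise InvalidStateError("conductivity must be non-negative")
    p = _p_exponent(beta)
    if grad is None:
        asm = assembler or P1Assembler(mesh)
        grad = asm.gradient(u)
    g2 = np.einsum("td,td->t", grad, grad)
    dirichlet = 0.5 * np.sum(mu * g2 * mesh.areas)
    infra = np.sum(np.power(mu, p) / p * mesh.areas)
    return float(dirichlet + infra)


def run_continuous_dmk(
    mesh: TriangularMesh,
    f: ForcingField | np.ndarray,
    mu0: np.ndarray | float = 1.0,
    opts: DmkOptions | None = None,
) -> ContinuousSolution:
    """Relax μ to the equilibrium of the continuous dynamics.

    Explicit update μ ← μ + dt·[(μ|∇u|)^β − μ] with the potential
    recomputed from the balance law at every step.  The step is accepted
    only if the transport functional does not increase (beyond
    1e-8·E₀); otherwise dt is halved, up to 10 times.  Stops when the
    relative rate of change of μ (after floor clipping) falls below
    ``opts.tol``.
    """
    opts = opts or DmkOptions()
    fv = f.values if isinstance(f, ForcingField) else np.asarray(f, dtype=float)
    mu = np.broadcast_to(np.asarray(mu0, dtype=float), (mesh.n_triangles,)).copy()
    if np.any(mu <= 0):
        raise InvalidParameterError("mu0 must be strictly positive everywhere")

    asm = P1Assembler(mesh)
    floor = opts.delta_floor
    dt = opts.dt
    u = asm.solve(mu, fv)
    grad = asm.gradient(u)
    gnorm = np.sqrt(np.einsum("td,td->t", grad, grad))
    energy = lyapunov_energy(mesh, mu, u, opts.beta, grad=grad)
    e0 = abs(energy) or 1.0
    trace = [energy]
    converged = False
    halvings = 0
    it = 0
    while it < opts.max_iter:
        it += 1
        growth = np.power(mu * gnorm, opts.beta)
        mu_new = np.maximum(mu + dt * (growth - mu), floor)
        if not np.all(np.isfinite(mu_new)):
            raise NumericalFailureError(f"non-finite conductivity at iteration {it}")
        u_new = asm.solve(mu_new, fv)
        grad_new = asm.gradient(u_new)
        gnorm_new = np.sqrt(np.einsum("td,td->t", grad_new, grad_new))
        energy_new = lyapunov_energy(mesh, mu_new, u_new, opts.beta, grad=grad_new)
        if energy_new > energy + 1e-8 * e0 and halvings < 10:
            dt *= 0.5
            halvings += 1
            it -= 1
            continue
        rate = np.max(np.abs(mu_new - mu) / (dt * np.maximum(mu, floor)))
        mu, u, grad, gnorm, energy = mu_new, u_new, grad_new, gnorm_new, energy_new
        trace.append(energy)
        if rate < opts.tol:
            converged = True
            break
    return ContinuousSolution(
        mu=mu,
        u=u,
        grad_norm=gnorm,
        flux_magnitude=mu * gnorm,
        iterations=it,
        converged=converged,
        energy_trace=np.asarray(trace),
        beta=opts.beta,
    )


def cut_flux(
    mesh: TriangularMesh,
    mu: np.ndarray,
    u: np.ndarray,
    vertex_set: np.ndarray,
) -> float:
    """Finite-element flux leaving a vertex set.

    For the P1 discretisation the net flux out of the patch around a
    vertex set S is ``Σ_{i∈S} (A(μ) u)_i``; when S contains the full
    source support and no sink support this equals the injected mass.
    """
    asm = P1Assembler(mesh)
    Au = asm.stiffness(np.asarray(mu)) @ np.asarray(u)
    idx = np.asarray(list(vertex_set), dtype=int)
    return float(Au[idx].sum())
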