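# Methods

`routex` extracts explicit weighted networks from routing-optimization
solutions in continuous 2D space, and from network-like images, in three
stages: (1) a continuous dynamical Monge–Kantorovich (DMK) solver on a
triangulated domain, (2) rule-based graph pre-extraction, (3) a
principled graph filter driven by the discrete DMK (Physarum / basis
pursuit) dynamics. This note records the models, the numerical choices,
and what the shipped synthetic problems do and do not probe.

## Continuous model

On Ω = [0,1]² with balanced forcing f = f⁺ − f⁻ (∫f = 0, no-flow
boundary), the transport density μ(t,x) ≥ 0 and potential u(t,x) evolve
as

    −∇·(μ∇u) = f,      ∂μ/∂t = (μ|∇u|)^β − μ,      μ(0,·) = μ0 > 0.

The bracket is read as the flux magnitude |q| = μ|∇u| raised to β, the
same form the discrete dynamics uses for the absolute potential drop.
The equilibrium minimises

    L(μ,u) = ½∫ μ|∇u|² dx + ∫ μ^{P(β)}/P(β) dx,   P(β) = (2−β)/β,

an operating (dissipation) cost plus an infrastructure cost. β = 1 is
shortest-path-like — at equilibrium |∇u| = 1 on the support of μ — and
β > 1 consolidates flow into branched networks. β < 1
(congestion-avoiding) and β ≥ 2 (P ≤ 0) are out of scope; options reject
them.

### Discretisation and integration

* u: piecewise-linear (P1) finite elements on vertices; μ and f:
  piecewise constant on triangles, attributed to barycenters.
* Meshes are structured: ndiv×ndiv square cells split along the
  lower-left→upper-right diagonal, then `nref` uniform midpoint
  quadrisections. Any conforming triangulation would do; the structured
  family keeps runs deterministic and makes refinement nesting exact.
* The pure-Neumann solve grounds one vertex and recentres u to zero
  mean; forcing balance is checked to 1e-10 before every solve.
* Time integration is explicit relaxation, μ ← μ + dt[(μ|∇u|)^β − μ],
  with default dt = 0.1. After each trial step the energy is recomputed;
  if it increased by more than 1e-8·E₀ the step is rejected and dt
  halved (at most 10 times). This guard makes the Lyapunov property a
  runtime invariant rather than a hope. A reference implementation of
  the same fixed point could use implicit Euler with Newton; the
  contract here is the equilibrium, not the trajectory.
* μ is floored at `delta_floor` = 1e-10 so the stiffness matrix stays
  invertible while unused triangles decay.
* Stopping: max_T |Δμ_T| / (dt·max(μ_T, floor)) < tol (default 1e-4),
  measured after floor clipping so fully decayed triangles stop
  contributing. β = 1 has degenerate directions along which μ decays
  only polynomially; such runs are flagged `converged=False` while the
  support properties (eikonal, flux balance) already hold to tolerance.
* Iteration budgets: the library default (`DmkOptions.max_iter`) is
  2000; the pipeline default is 20000 because the branched study runs
  (β = 1.1, ndiv = 32) need ≈10⁴ steps at dt = 0.1 to meet tol = 1e-4,
  and the vein statistics below are only meaningful at equilibrium.

### A discretisation artifact worth knowing

On structured meshes the equilibrium band alternates between the two
triangle orientations: consecutive triangles of the band often share
only a vertex, not an edge (a checkerboard pattern). This is why
pre-extraction rule I (edge-*or*-vertex sharing) exists and is the
default; connectivity checks on the raw field must use vertex-sharing
adjacency.

## Graph pre-extraction

Triangles with μ*(b_i) ≥ δ (default δ = 0.01) are kept. Nodes/edges:

* **Rule I** — node per kept triangle at its barycenter; edge when two
  kept triangles share a grid edge or grid vertex.
* **Rule II** — as I but grid-edge sharing only; node degree ≤ 3.
* **Rule III** — the grid vertices and grid edges of kept triangles.

Weights: **AVG** w_ij = (μ_i+μ_j)/2, or **ER** w_ij = μ_i/d_i + μ_j/d_j
with d_i the node degree in the extracted graph (computed after
thresholding). ER conserves the total density exactly:
Σ_e w_e = Σ_{d_i>0} μ_i; the package treats this identity as exact
(tested to 1e-12 with compensated summation). Rule III always uses AVG
(the mean of the kept triangles adjacent to the grid edge; boundary
edges take their single neighbour's value). Isolated nodes are retained
but excluded from the conservation sum. Edge lengths are Euclidean by
default, with a unit-length mode.

## Terminal selection

Nodes whose positions lie in supp f⁺ / supp f⁻ are eligible. A node is
kept as a terminal if it is a vertex of the convex hull of the eligible
positions of its sign, or if its betweenness centrality is below τ_BC
(default 0.1). Choices made where the procedure is underdetermined:

* betweenness is the normalised, unweighted shortest-path betweenness on
  the whole pre-extracted graph (a normalised scale is the only one on
  which a universal τ_BC = 0.1 makes sense);
* "in the convex hull" is read as *hull vertex* (otherwise every
  eligible node qualifies trivially); collinear sets keep the two
  extreme points;
* nodes eligible for both signs (overlapping supports) are assigned to
  neither, with a warning.

Fluxes are distributed uniformly per connected component C_m:
f_i = +1/|S⁺∩C_m| on sources, −1/|S⁻∩C_m| on sinks, so every component
is closed. Components lacking a sign are flagged inactive.

## Discrete filter

On the pre-extracted graph with signed incidence B (edges oriented from
the lower to the higher node id), lengths ℓ_e and μ_e(0) = w(e):

    f = B diag(μ/ℓ) Bᵀ u   (Kirchhoff),
    μ_e' = (μ_e/ℓ_e·|Bᵀu|_e)^{β_d} − μ_e,

with energy ½Σ μ_e(Δu_e/ℓ_e)²ℓ_e + ½Σ μ_e^{P(β_d)}/P(β_d)·ℓ_e. The
same explicit, energy-guarded integration and stopping rule are used
(floor 1e-12; one grounded node per active component; the Kirchhoff
residual ‖B·flux − f‖∞ is tracked every accepted iterate and stays below
1e-8). For β_d = 1 the energy is convex and the equilibrium flux is the
minimum-cost flow with costs ℓ_e; the test suite verifies this against
an independent LP oracle on all 995 non-isomorphic connected graphs with
≤7 nodes plus seeded 8-node samples (worst per-edge deviation ~5e-12).
Since the equilibrium does not depend on dt, those β_d = 1 runs use
dt = 0.45 to shorten near-degenerate instances (two almost equal path
costs converge at a rate proportional to the cost gap).

Pruning keeps edges with μ*_e ≥ δ_d (default 1e-3, absolute; a relative
mode is available because the reference procedure does not say whether
δ_d is scaled by max μ*). Weights: **BPW** = μ*_e, **IBP** = the
pre-extraction weight. Inactive components are dropped by default
(`drop_inactive=False` passes them through untouched); running the
dynamics there would be meaningless — f ≡ 0 just sends μ → 0.

A scale worth noting: with uniform per-terminal fluxes, a leaf edge
serving one of k sinks carries |q| = 1/k, so its equilibrium
conductivity is k^{−β_d}; δ_d = 1e-3 therefore starts pruning leaf veins
once k ≳ 500 (β_d = 1.1). This couples the pruning threshold to the
terminal count on purpose — it is exactly the "filter redundancy"
behaviour — but it means vein statistics depend on how many terminals
the selection step admits.

## Evaluation metrics

* ŵ_q (default q = 2): Ω is split into P = (N−1)² rectangles (default
  N = 11) from N-regular axis partitions; cells are half-open with the
  top/right boundary closed, so boundary points belong to exactly one
  cell. Per cell, the sum of edge weights (edges straddling two cells
  count ½ per side, using the endpoint positions) is compared to the raw
  density mass of the kept triangles; ŵ_q = (1/P)[Σ_α|·|^q]^{1/q}.
* L(G) = Σℓ_e, unit or Euclidean; any L_max normalisation is over a
  user-supplied ensemble, never hardcoded.
* Vein lengths: maximal chains of degree-2 nodes are contracted, summing
  segment lengths; closed all-degree-2 cycles become one vein. The vein
  histogram (default 30 equal-width bins, raw counts) is fitted with
  P(ℓ) = P₀e^{−γℓ} by nonlinear least squares on (bin centre, count);
  counts (not densities) are fitted because the reference magnitudes of
  P₀ are count-scaled, and no binning/fit method is published — these
  are stated package choices.

## Image input

Pixel intensity (ITU luminance for colour images, or a named channel),
block-mean downsampled and mapped to [0,1], acts as an artificial μ* on
the pixel grid; the grid is mapped into [0,1]² preserving aspect ratio
(longest side = 1, row 0 on top). Masked pixels (≥ δ_img) become nodes;
4-connectivity mirrors rule II, 8-connectivity rule I; AVG/ER apply
unchanged (ER conserves the masked intensity sum exactly). Because the
β_d > 1 filter produces trees, loops are recovered by: feeding the
filter a maximum-weight spanning forest of the pre-extracted graph, then
re-inserting the pre-extraction shortest path between any two
terminals/leaves of the filtered graph whose pre-extraction hop distance
is ≤ radius (default 2) but whose filtered distance is larger. This
reconstruction of the loop-recovery step is a package design choice; the
notion of "close by" (hop radius) and the candidate set
(terminals + leaves) are the open parameters.

## Synthetic study conditions

The shipped fixtures emulate standard routing benchmarks: two facing
rectangles; four corner sources with a central sink; a central disk
source (r ≤ 0.1) with an annular sink (0.1 < r ≤ √0.45) used for the
vein-length study; μ0 families uniform / parabola-like bump /
delta-like Gaussian peak (σ = 0.1); seeded random disjoint rectangle
layouts; and a deterministically rendered loopy skeleton image. They are
deliberately noise-free and perfectly balanced — real imaging data has
intensity noise, uneven illumination and gaps, none of which these
fixtures exercise; passing tests demonstrate correctness of the
algorithms, not robustness to imaging artifacts.

Default problem sizes are chosen so a full study run (ndiv = 32,
≈2·10³ triangles, ≈10⁴ relaxation steps, filter on ≈2·10³ edges)
completes in about a minute on one core; the tests use ndiv = 8–32.

## Known limitations

* The vein-length scale of a filtered network is partly set by the mesh:
  junction spacing cannot fall below the barycenter spacing, so the
  fitted decay rate γ of the vein histogram grows with mesh resolution
  and shrinks with β. Under the package defaults (ndiv = 32, β = 1.1,
  β_d = 1.1, 30 bins) the disk/annulus study yields γ ≈ 57 over ≈350
  veins; doubling resolution or raising β moves γ by factors of 2–6.
  Treat γ comparisons across configurations with care.
* Equilibrium energies at strong branching (β ≳ 1.2) converge slowly
  under mesh refinement (the support is singular); the <5% refinement
  stability holds for β ≤ 1.1 at the tested sizes.
* β = 1 runs stop by iteration cap, not by the rate criterion (the
  dynamics is degenerate along shortest-path ties); equilibrium
  properties hold regardless.
* Exact length ties on structured meshes are non-generic inputs for the
  β_d > 1 filter; tie-broken (jittered) lengths guarantee forest output,
  exact ties may leave cycles of equal-cost alternatives.
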