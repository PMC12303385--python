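# Methods

## Model

A leaf venation network is a connected planar graph with `n_n` nodes and
`n_e` edges; edge i carries a length ℓᵢ and width wᵢ, node j a drainage
area aⱼ. One node — the petiole — injects fluid; all others drain it. Flow
is steady and laminar, so each vein acts as a Hagen–Poiseuille pipe,

    fᵢ = (cᵢ/ℓᵢ) Δpᵢ,      cᵢ = wᵢ⁴   (proportionality constant 1).

With the signed incidence matrix B (+1 at an edge's tail, −1 at its head)
and conductances C_eff = diag(cᵢ/ℓᵢ), Kirchhoff's law B f = s closes the
system: A p = s with the weighted graph Laplacian A = B C_eff Bᵀ, and
f = C_eff Bᵀ p ≡ G s. A has rank n_n − 1 on a connected network; the
pressure gauge is fixed by grounding one node, which is equivalent to the
pseudo-inverse solution for balanced loads because only pressure
differences enter the fluxes.

The xylem formulation is used throughout (source at the petiole, sinks in
the lamina); the phloem problem is its mathematical dual and needs no
separate treatment.

### Fluctuating sinks

Drainage in a living leaf is not static. The load ensemble has one member
per sink node k:

    s_j(k) = 1                                    j = source,
    s_j(k) = −a_j (s_avg + δ_jk σ) C(k)           otherwise,

with s_avg = (1 − σ)/(n_n − 1) and
C(k) = (σ a_k + s_avg Σ_sinks a_j)⁻¹, which guarantees Σ_j s_j(k) = 0
analytically (total inflow equals total drainage for every member). The
amplitude σ ∈ [0, 1] interpolates between purely area-proportional
drainage (σ = 0, a single static load) and a fully concentrated moving
sink (σ = 1: s_k = −1, all other sinks 0, independent of areas).
Ensemble averages use uniform weights 1/(n_n − 1); the σ = 0 ensemble is
collapsed to its single distinct member.

### Optimal conductivities

The network is assumed to minimize the ensemble-averaged dissipation
P = Σᵢ ⟨fᵢ²⟩/c_eff,ᵢ subject to a fixed material cost Σᵢ ℓᵢ cᵢ^γ.
Stationarity gives cᵢ ∝ ⟨fᵢ²⟩^{1/(1+γ)}, applied as a fixed-point
iteration: solve the flow for every ensemble member, update
cᵢ ← ⟨fᵢ²⟩^{1/(1+γ)}, repeat. γ defaults to ½, for which the budget
Σ ℓ w² is the total vein volume; larger γ penalizes thick veins more and
flattens the width hierarchy.

Two facts shape the procedure:

* **The landscape is highly non-convex.** Iterating from different small
  perturbations of a uniform state reaches topologically different local
  optima of nearly equal power. The iteration is therefore initialized at
  the observed data widths, c⁰ = (w^data)⁴, selecting the local optimum
  nearest the real network. This is a modeling commitment, not a numerical
  convenience: all comparisons are against that particular optimum.
* **Conductivity units are arbitrary during iteration.** The material
  budget only sets the overall scale, so no per-iteration rescaling is
  done; after convergence the widths w = c^¼ are normalized once so their
  mean equals the mean data width (ŵ = w · ⟨w^data⟩/⟨w^model⟩).

Normalized widths below 10⁻³ × mean data width are reported as exactly
zero: the optimum genuinely abandons edges (loops die at σ = 0), and the
classification threshold separates the surviving hierarchy from edges in
numerical free fall.

### Convergence criterion

Iteration stops when max|Δw|/max(w) < tol (default 10⁻⁶), with w = c^¼,
or after `max_iter` = 5000 steps (non-convergence is flagged, not fatal).
The criterion is applied to widths rather than to c deliberately: c = w⁴
compresses the small-width tail so strongly that a still-dying vein at a
few percent of the maximum width moves less than any sensible tolerance
on c, which would freeze spurious loops into the result. The monitored
dissipation (reported per iteration, rescaled to constant material cost
using the invariance of fluxes under global conductivity rescaling) is
non-increasing along the iteration, which is asserted in the tests.

### Numerical linear algebra

The grounded reduced Laplacian is factorized once per iteration (dense
Cholesky below 1500 nodes, sparse LU above) and reused for all ensemble
members, so one iteration costs one factorization plus a blocked solve.
During optimization, conductivities are floored at 10⁻¹⁸ × max(c) when
assembling A so the system stays non-singular while veins die. The floor
matters: a floored edge's flux pins its width near floor^{1/3} of the
network scale, so the floor must sit far below the fourth power of the
zero-width threshold — 10⁻¹² (which would pin dead edges at exactly the
10⁻³ classification cut) is too high, 10⁻¹⁸ leaves three decades of
margin. Conservation ‖B f − s‖∞ ≤ 10⁻⁹ ‖s‖∞ is enforced with up to three
steps of iterative refinement on the factorized system.

### Subsystem decomposition

Full leaves have 10⁴–10⁵ nodes; iterating a global factorization is then
impractical. The leaf is split into K ≈ 10 spatial clusters (k-means on
node coordinates, fixed seed, clusters relabeled by minimum node index
for reproducibility). For each cluster Q, loads translate exactly through
s̃ = Z s with Z = M (I − J G): J keeps the incidence entries of edges
crossing the cluster boundary, M selects the Q rows, and G = C_eff Bᵀ A†
is the flux-response matrix of the initial conductivities. With unchanged
conductivities the translated solve reproduces the full-system fluxes on
interior edges to machine precision (asserted). During optimization each
subsystem iterates its interior conductivities to convergence while the
exterior stays frozen — justified exactly when the initialization is
already near the optimum, which the data-width initialization provides.
Z and G are computed once; one sweep over subsystems is the default.

Crossing edges belong to no interior and are never iterated. They are
assigned the single-step optimality update ⟨f²(c⁰)⟩^{1/(1+γ)} evaluated
at the initial state: the converged interiors live on the conductivity
scale fixed by the loads, not on the data-width⁴ scale, and leaving
crossing edges on the data scale would corrupt the final global width
normalization. Near the data-selected optimum the one-step value is
itself close to the fixed point. With K = 1 the subsystem path reduces to
the monolithic optimizer exactly (bit-for-bit, asserted).

## σ estimation

L(σ) = ⟨(wᵢ^data − ŵᵢ^model(σ))²/wᵢ^data⟩ᵢ weights each edge by 1/width,
equivalent to giving every vein pixel of the original image equal weight.
Each grid evaluation is a full optimization warm-started from the data
widths (never from the previous σ's solution, preserving the
local-optimum selection). The default grid is {0, 0.02, …, 0.30} —
observed optima concentrate at small σ — with the argmin refined by
parabolic interpolation through its bracketing points; boundary minima
are flagged but returned, since σ* = 0 and σ* = 1 are meaningful limits.

## Murray's law for reticulate networks

Classical Murray's law balances r_p^α against Σ r_d^α at a branch node
with α = 3 for leak-free laminar flow in a tree. In a loopy network edge
flow directions depend on the drainage pattern, so the sums are resolved
per ensemble member and averaged:

    R_b^{in/out}(α) = ⟨ Σᵢ I_b,i^{in/out}(k) · r_i^α ⟩_k,

with r = w/2 and the indicator classifying edge i at branch node b
(degree > 2) as inflowing or outflowing under sink position k; fluxes
below 10⁻¹² of the ensemble maximum are in neither class, and the number
of terms per sum legitimately varies across members. The exponent is
fitted by minimizing L(α) = ⟨(R_b^out − R_b^in)²⟩_b on a grid (default
[2, 4], step 0.01) with parabolic refinement.

Two deliberate choices:

* **The petiole is excluded from the branch set** even when its degree
  exceeds 2. It has no incoming vein; its "residual" would equal the full
  unit inflow, orders of magnitude above any genuine branch-node
  residual, and would dominate the loss.
* **Sink-leak correction.** The model drains fluid at branch nodes, so
  even a perfect tree violates the leak-free law: at the σ = 0 fixed
  point w³ ∝ |f| and conservation leaves residual_b = −κ a_b with one
  global κ > 0. The correction fits κ by least squares
  (κ = −Σ r_b a_b / Σ a_b²) and recenters the residuals; on a converged
  tree the cancellation is exact up to the optimizer tolerance
  (observed ≲10⁻¹³ relative). Gaussian-kernel smoothed residual curves
  versus parent-vein width (bandwidth 0.2 decades in log₁₀ width) are
  provided for inspection.

### Known desk-scale limitations of the α fit

The loss minimum is *not* invariant under a global width rescaling:
L_λ(α) = λ^{2α} L(α), so the argmin shifts by ≈ −2 ln λ · L/L″ whenever
the minimum loss is positive. On large networks the minimum is deep and
the effect negligible; on the few-hundred-node synthetic lattices used
here the sink leak keeps L(α*) well above zero and the fitted exponent
inherits both a scale sensitivity and a finite-size bias of order −0.1/n̄
per branch node share: measured α*(σ = 0) ≈ 2.87 at ~290 nodes, 2.93 at
~500, 2.97 at ~900, approaching 3 as the leak per branch node shrinks.
The positive shift under sink fluctuation is robust at every size
(α*(σ = 0.094) ≳ 3.0 on the ~500-node lattice). Widths enter in the
units of the input data; all reported fits use the synthetic generator's
unit (mean width 1).

## Extraction

Binary masks are skeletonized with a medial-axis transform; the local
full width at a skeleton pixel is 2d − 1 where d is the Euclidean
distance to background (the −1 accounts for the half-pixel overshoot of
center-to-center distances; a 5-px bar reads d = 3). Endpoints are
skeleton pixels with one 8-neighbor, branch points those with three or
more; adjacent branch pixels merge into one node at their centroid. Edges
are traced by walking the skeleton between node pixels; the edge width is
the mean of the width raster along the path, and the edge length is
measured along a 5-px moving-average smoothed polyline of the path
(raw pixel-step sums overestimate near-axial paths whose skeleton
zigzags between adjacent rows by up to ~18%). Pruning merges nodes
within 3 px (union–find, merged position = mean) and contracts every
degree-2 node (length = sum, width = length-weighted mean); isolated
skeleton cycles are anchored at two synthetic nodes. Pruning is
idempotent. The source is the node nearest a user-supplied petiole
coordinate.

Drainage areas are boundary-clipped Voronoi cell areas; the cells
partition the lamina, so Σ aⱼ equals the boundary area to numerical
precision. When no boundary polygon is supplied, the concave hull
(alpha shape) of the node cloud is used — the tightest single simple
polygon covering ≥99% of the nodes, falling back to the convex hull.

## Synthetic data

The generator emulates the statistical features of image-extracted
networks that matter to the model: irregular node placement (triangular
lattice, positional jitter ±0.2h per coordinate), heterogeneous drainage
areas (from the actual clipped Voronoi cells), abundant loops and
branch nodes (triangular rather than square lattice), and a petiole
appended at the lamina base. Edges come from the Delaunay triangulation
filtered to local links (<1.7h). Initial widths are uniform with a ±1%
multiplicative perturbation (seeded) — the small symmetry-breaking that
selects a local optimum. The standard experimental lattice is an
ellipse of length 2 and width 1 at spacing h = 0.06 (~500 nodes), small
enough that the full test suite and the acceptance script run in
minutes on one CPU; the model itself handles larger inputs through the
subsystem path.

Pseudo-data for parameter-recovery experiments is manufactured by the
model itself at a known σ*, with optional multiplicative lognormal noise
and a width floor of 10⁻³ × mean width (extracted data contains no
zero-width veins). Recovery of σ* = 0.3 from noisy pseudo-data succeeds
within ±0.05 on a 16-point grid; note this tests self-consistency of the
inference machinery, not the model's adequacy for real leaves.

What passing these tests does **not** show: real masks carry segmentation
noise, curved veins, and width gradients along edges that the rendered
fixtures lack; the pseudo-data inverse experiments share the model's own
physics (no model misspecification); and the synthetic lamina is convex,
so the alpha-shape boundary is easier than a real leaf outline.

## Degenerate inputs and tie-breaking

Zero-width edges are rejected on input (data must connect the leaf);
self-loops are rejected; duplicate node ids fail loading. Ties in the
in/out classification (|f| below 10⁻¹² of the ensemble maximum) drop the
edge from both Murray sums. k-means uses a fixed seed and deterministic
relabeling; subsystems are visited in label order. All generators are
pure functions of (parameters, seed).
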