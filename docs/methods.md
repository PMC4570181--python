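# Methods

## Forward model

Photon transport in highly scattering tissue is modeled by the diffusion
approximation with a Robin boundary condition:

    −∇·(D ∇φ) + μ_a φ = q   in Ω,      φ + 2 A_n D ∂φ/∂ν = 0   on ∂Ω,

with fluence φ, source density q, absorption μ_a (mm⁻¹), reduced
scattering μ_s′ (mm⁻¹), diffusion coefficient D = 1/(3(μ_a + μ_s′)), and
A_n the refractive-index mismatch factor computed from the standard
polynomial fit of the effective Fresnel reflectance
(R_eff = −1.4399 n⁻² + 0.7099 n⁻¹ + 0.6681 + 0.0636 n,
A_n = (1+R_eff)/(1−R_eff); default n = 1.37, so A_n ≈ 3.25).

Discretization uses linear (P1) tetrahedral elements with closed-form
element matrices (stiffness D·V·∇λ_i·∇λ_j; mass V/10 diagonal, V/20
off-diagonal; Robin face term (1/2A_n)·Area·(1+δ_ij)/12). The assembled
operator K is symmetric positive definite and factorized once per
channel (sparse LU); sensitivity rows are obtained by one adjoint solve
per unique detector node, which equals the forward construction to
solver precision because K is symmetric.

Two sensitivity-matrix modes exist. `emission-only` treats each matrix
entry as the emission-channel Green's value between a source node and a
detector node (bioluminescence/Cerenkov style). `excitation-weighted`
multiplies each entry by the excitation fluence at the source node from
the corresponding boundary excitation point (fluorescence style, Born
approximation); this is the default for the two-source cylinder study,
which emulates a fluorescence acquisition with 4 boundary excitation
points and a 160° opposite-side detector arc per excitation. The
measured quantity is nodal boundary fluence rather than Fick-law
exitance: the two differ per detector by a positive constant factor,
which does not change the geometry of the inverse problem.

FEM accuracy is verified against the infinite-medium point-source
Green's function φ(r) = exp(−μ_eff r)/(4π D r), μ_eff = √(μ_a/D): on a
fine homogeneous cylinder the relative error is below 15% (mean ≈ 1–3%)
for r ∈ [2, 6] mm from the source.

## Phantom generation

The cylinder mesher is a deterministic structured tetrahedralization:
a disk triangulated as concentric rings (ring i carries 6i nodes) is
stacked along z and each prism is split into three tets with a
face-local smallest-index diagonal rule, which keeps adjacent prisms
conforming. The mesh is byte-identical across runs for fixed arguments;
total volume is within 2% of π r² h (a minimum of 4 rings caps the
polygonal faceting deficit); at ~1 mm edges the 20 mm phantom has
5–7k nodes, comparable to typical published discretizations of the same
geometry.

The 4-tissue phantom attaches muscle/lung/bone/heart optical
coefficients at the excitation and emission wavelengths from the
packaged table (`data/cylinder_4tissue_optics.csv`). The inclusion
cross-section (two lung cylinders, a bone column, a heart ellipsoid) is
a qualitative layout and fully configurable: localization accuracy is
governed by the source positions, which are exact. Sources are spheres
of radius 1 mm and density 1 (arbitrary units) whose centers snap to the
nearest mesh node; the snapped node is the ground-truth center, so
location error is measured on the mesh itself. A single-channel mouse
tissue optics table (`data/mouse_tissue_optics.csv`) ships as a preset
for user-supplied labeled meshes; no in-vivo dataset is distributed.

What the synthetic study does *not* emulate: camera noise and
autofluorescence background (noise is optional, Gaussian, off by
default), free-space light propagation to a detector, spectrally
resolved acquisition, and real segmentation/registration error of an
animal model. Passing the phantom study therefore demonstrates
correctness of the operator/solver chain under an exactly known forward
model (an "inverse crime" in the favorable sense), not in-vivo accuracy.

## Inverse solvers

All solvers act on the column-normalized operator A·D⁻¹ (D = diag of
column norms), standard sensitivity normalization in this field; without
it the depth-dependent column scale biases every reconstruction toward
the phantom interior (the raw back-projection AᵀΦ peaks near the center
rather than at the sources). Solutions are mapped back to physical
units afterwards.

**Linearized Bregman (lbsr).** The two-line iteration with elementwise
soft thresholding. Its fixed point solves
min μ‖S‖₁ + (1/2δ)‖S‖₂² s.t. AS = Φ, so the l1 term is only active when
μδ reaches the solution amplitude (the exact-regularization regime).
Defaults: δ = 1/σ_max(A)² (stability bound; σ_max by 60 seeded power
iterations), μ = 2·amp/δ where amp is the sup-norm of a 100-iteration
LSQR least-squares estimate — a deterministic, data-driven amplitude
scale with a safety factor of 2. Stagnant sweeps (no threshold
crossing, iterate exactly unchanged) are compressed by "kicking":
inactive dual components jump by the number of identical sweeps needed
for the next crossing, leaving the visited iterates unchanged. Stopping
follows the relative-change rule ‖Sᵏ⁺¹−Sᵏ‖/‖Sᵏ‖ ≤ ε = 10⁻³ (skipped
while ‖Sᵏ‖ = 0), with a cap of 5000 sweeps and an abort on non-finite
iterates (diagnostic suggests δ ≤ 1/σ_max²). An optional nonnegativity
projection after shrinkage is off by default; on the two-source study it
is inert because operator and data are positive.

**Tikhonov CG (l2cg).** Conjugate gradient on the normal equations
(AᵀA + λI)S = AᵀΦ, matrix-free; default λ = 10⁻⁶·max diag(AᵀA),
tolerance 10⁻⁶. Non-convergence warns and flags the result rather than
raising.

**Split Bregman (l1sb).** Variable splitting d ≈ S with a quadratic
CG subproblem, d = shrink(S+b, μ/λ_p), and Bregman update
b ← b + S − d; penalty λ_p = σ_max²/10. Its μ default is the classical
lasso heuristic 0.01·‖AᵀΦ‖_∞ (1% of the smallest weight that zeroes the
solution) — appropriate here because this solver minimizes the l1
objective directly, whereas the same formula applied to the linearized
Bregman threshold would leave the shrinkage inert (crossed on the first
sweep, never active again) and reduce that iteration to a thresholded
Landweber method. This asymmetry is why `default_parameters` takes the
solver name into account.

## Evaluation

* **Location error**: Euclidean distance (mm) between the true
  (snapped) center and a reconstructed center.
* **Center extraction**: nodes ≥ 50% of the reconstruction maximum are
  clustered by mesh adjacency; each cluster's center is its
  energy-weighted centroid; centers are matched to true sources
  greedily by distance without replacement. The 50% centroid is stable
  under refinement and reduces to the node position for single-node
  reconstructions.
* **CNR**: |mean_ROI − mean_BG| / √(w_ROI·var_ROI + w_BG·var_BG) with
  volume-fraction weights and lumped-nodal-volume weighting inside each
  group; ROI = nodes within 2 mm of the true centers. The absolute CNR
  value depends on this formula choice, so between-method *ordering* is
  the meaningful comparison.

## Two-source study: behavior and numbers

At 1.1 mm target edge (5149 nodes), noiseless data: the Tikhonov-CG
baseline localizes both sources exactly (LE = 0.00/0.00 mm), Split
Bregman is one node off (≈0.97 mm), and the linearized Bregman solver
terminates by the relative-change rule after ≈700 sweeps with its
maximum exactly on the true nodes and LE ≈ 0.16 mm from partial
neighbor atoms inside the 50% cluster (the iterate still carries ~12%
relative residual at the printed tolerance — the rule measures iterate
motion, not data fit). CNR ordering is LBSR > l1-SB > l2-CG. These
numbers come from `scripts/acceptance.py` and the acceptance tests; the
localization tolerance used in tests is half the mesh edge (0.55 mm),
i.e. agreement at node resolution.

Known limitations: on this strongly coherent operator the l1 limit is
not a clean two-atom solution — running far past the stopping rule lets
secondary atoms drift in and out of the 50% cluster (LE oscillates
between ~0.0 and ~0.8 mm over tens of thousands of sweeps), so the
printed relative-change rule is kept as the defined endpoint. The
node-footprint of the Bregman solution at that endpoint (≈66 nodes
above 10% of max) is larger than that of the *converged, normalized*
Tikhonov solution (≈16 nodes), i.e. the classical "l2 is more
scattered" picture does not hold under uniform sensitivity
normalization at this stopping tolerance. Runtimes are
hardware-dependent and not treated as reproducible quantities.

## Problem sizes

Default study resolution is 1.1 mm (≈5.1k nodes, ≈1.9k measurement
rows, ≈3.7k candidate columns), chosen as the package's standard desk
configuration; the pipeline scales to finer meshes with the dominant
costs being the per-detector adjoint solves and the dense matrix
products of the iterative solvers.
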