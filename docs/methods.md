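# Methods

This note documents the models, discretizations, numerical choices and
known limitations of the package. Empirical statements below are limited
to what the test suite and `scripts/acceptance.py` themselves compute.

## Governing model

Quasi-static volume conduction: ∇·(σ∇φ) = ∇·J_P inside the head with a
homogeneous Neumann (no-flux) condition on the scalp. The source is an
ideal current dipole, either as the point limit (moment **M** [A·m] at
r₀) or as an explicit source/sink monopole pair at separation d carrying
current I = |M|/d. All solvers use the convention that the infinite-medium
potential of the dipole is φ∞ = **M**·(r−r₀)/(4πσ|r−r₀|³). The solution
of the Neumann problem is defined only up to a constant; every solver
removes it by a mean-zero deflation constraint and all reported potentials
are average-referenced.

## Geometry and meshing

Head models are nested concentric shells. Two presets carry the published
benchmark parameters:

| model | outer radii [cm] | conductivity intervals [S/m] |
|---|---|---|
| three-layer | brain 8.0, skull 8.6, scalp 9.2 | 0.22–0.67, 0.0016–0.033, 0.28–0.87 |
| four-layer | brain 7.6, CSF 8.0, skull 8.6, scalp 9.2 | 0.22–0.67, 1.7696–1.8104, 0.0016–0.033, 0.28–0.87 |

The skull may instead be radially anisotropic with the fixed optimized
pair σ_r = 0.0093, σ_t = 0.015 S/m; this pair is held constant across
Monte-Carlo realizations while the isotropic layers are redrawn (the
randomization of an anisotropic skull magnitude is not specified by the
benchmark; holding it fixed is the minimal assumption).

Volume meshes are built by radially extruding a single spherical surface
triangulation (Fibonacci lattice + convex hull): every interface sphere is
triangulated by the same angular mesh scaled to its radius, radial gaps are
filled with prisms split into three tetrahedra by a globally consistent
smallest-index diagonal rule, and the innermost gap is capped by tets at
the center. Consequences used throughout:

* interface triangles are exactly faces of the volume tetrahedra (the
  conformity the hybrid coupling requires),
* every tet lies inside one tissue shell, so labels are exact,
* meshes are deterministic per (density, seed); the seed randomly rotates
  the angular lattice.

Mesh-size controls: surface point count (2n−4 triangles per shell), radial
layer counts per region, a radial grading exponent concentrating brain
layers near the cortex, and a **polar-cap fraction**: a share of the
surface points (default 25% within a 25° cap) is packed around the +z
axis. The validation design places every dipole on the +z axis, so the
scalp-potential peak always sits above the pole; at the benchmark's fixed
element budgets the cap is what makes the peak resolvable for the
98%-eccentric sources (the dipole then lies 1.6 mm beneath the brain
surface while uncapped elements are ~9 mm wide). Units are SI internally;
centimeters appear only in model specifications.

Default densities are pinned near the published element counts: three-layer
PI-FEM ≈ 7.1k nodes / 38k tets, BEM ≈ 3.0k surface triangles over three
shells, hybrid ≈ 1.8k interface triangles with an 11k-tet FE part;
four-layer PI-FEM ≈ 14k nodes / 75k tets, hybrid ≈ 3.4k interface
triangles / 31k FE tets. Exact counts of the original irregular meshes are
not reproducible; these land within a quarter of them.

## BEM

Constant collocation elements: potential and normal derivative are
per-triangle constants collocated at centroids, interpreted as element
*means*. The influence integrals D1 = ∫Φ dS and D2 = ∫∂Φ/∂n dS use exact
flat-triangle formulas (the edge-decomposition of the 1/R potential
integral; the van Oosterom–Strackee signed solid angle), valid arbitrarily
close to the element, so no near-singular quadrature is needed; the
self-element D2 is identically zero and the collocation coefficient is 1/2
(smooth-point value at a face centroid).

The multi-region assembly writes one boundary integral equation per region
(Poisson with the dipole volume term in the innermost region, Laplace
outside), merges interface unknowns through continuity of potential and of
normal current density (with explicit normal-direction signs), and imposes
zero flux on the scalp. The dipole volume term is entered as its **exact
element mean** (the gradient of the exact 1/R integral with respect to the
dipole position, central-differenced at machine-level accuracy) rather
than its centroid value: for near-cortical dipoles the centroid sample
aliases the source peak so strongly that the discrete compatibility
condition (zero net injected current, measurable as the left-null-vector
component of the right-hand side) is violated at the tens-of-percent
level, and the solve degrades catastrophically; with element means the
violation drops by two to three orders of magnitude. This is consistent
with the mean-value semantics of the unknowns themselves.

The assembled square system retains the constant null space; it is solved
as a dense augmented (Lagrange) system pinning the mean element potential,
with an extra consistency column absorbing the residual compatibility
defect. Per conductivity draw the matrix is dipole-independent, so sweeps
factorize once and back-substitute per dipole.

## PI-FEM

Linear tetrahedra with per-element symmetric positive-definite
conductivity tensors: isotropic σI, or the radially anisotropic rule
σ_r r̂r̂ᵀ + σ_t(I − r̂r̂ᵀ) evaluated at the element centroid (reducing
exactly to the isotropic rule when σ_r = σ_t). Element stiffness
K^e = V (∇N) σ (∇N)ᵀ with the constant P1 gradients. The dipole load is
the partial-integration form b_i = ∇N_i·**M** on the host tet (zero-sum by
construction); a two-monopole variant distributes ±I over the host tets of
the pair. A dipole on a face is perturbed deterministically into the
nearest tet. The singular pure-Neumann system is solved with a sparse
augmented mean-zero factorization; the returned solution must satisfy
‖Kφ−B‖ ≤ 10⁻¹⁰‖B‖ or the solver raises (any solver meeting this residual
contract is acceptable; a direct factorization is used). Per-region
unit-conductivity stiffness matrices are cached so Monte-Carlo draws only
rescale and re-add them.

## Hybrid BE–FE

Region assignment rules: the region containing the dipoles must be BE;
anisotropic regions must be FE; here the brain is BE and all outer shells
FE. Coupling on the shared interface (whose triangles are FE faces by
construction):

* *potential*: each BE element potential is replaced, by substitution in
  the BE collocation rows, with the mean of its triangle's three FE nodal
  potentials — the interface potential unknowns are eliminated and the
  system stays square; the relation holds exactly in the solution by
  construction.
* *current*: the FE weak-form surface term over the interface is expressed
  through the BE flux unknowns with opposing normals,
  σ_FE ∂φ/∂n_FE = −σ_BE p̄, contributing exactly −σ_BE p̄_T A_T/3 to each
  vertex of triangle T (exact integral of a P1 hat function against a
  constant — no quadrature error).

The global system couples the sparse FE stiffness with the dense BE block
and is solved in one step: the FE block (deflated by a mean-zero Lagrange
constraint fixing the single global constant) is factorized sparsely and
eliminated from the BE rows; the dense Schur complement in the flux
unknowns is LU-factorized; per dipole only the BE source vector changes.
The BE source term uses the same exact element means as the standalone
BEM. Net interface current, a free quantity of the discretization, comes
out balanced to a small fraction of the gross flux (asserted in tests).

## Validation pipeline

`run_example` performs the Monte-Carlo studies: per realization one
conductivity draw (uniform per layer within its interval) is shared by all
methods and dipoles — the pairing that makes Wilcoxon signed-rank
comparisons meaningful; six eccentricities (50–98% of the brain radius, on
the +z axis) × two orientations (radial ẑ, tangential x̂) are solved per
method; RDM and MAG are computed against the analytic solution evaluated
at each method's own evaluation points (scalp element centroids for BEM,
scalp nodes for FEM/hybrid). Meshes are built once per (model, method);
conductivity changes re-assemble but never re-mesh. Sweeps checkpoint per
realization and re-run bit-identically for a fixed config and seed.
`calibrate_matched_cost` optionally rescales per-method densities until
measured per-solve wall-clock matches within ±20%; by default the pinned
published-count densities are used.

The analytic reference solves, per spherical-harmonic degree n, a small
interface system for the layer coefficients with radius-scaled bases
(r/r_layer)^ν, where the anisotropic radial exponents solve
ν(ν+1) = (σ_t/σ_r)n(n+1); the primary field is written in ratio form
(b/r)^(n−1)/r² so no overflow occurs at high degree. The series is
truncated when five consecutive terms fall below a relative tolerance
(default 10⁻¹⁰, default cap n = 400; ~98%-eccentric dipoles evaluated at
the scalp converge within a few hundred terms because the term ratio is
set by b/r_scalp ≈ 0.85). On-axis dipoles keep the clean P_n (radial) /
P_n¹ cos φ (tangential) split; off-axis placement is rejected rather than
approximated.

## Problem sizes used by tests and the acceptance script

Unit and property tests run on coarse meshes (hundreds of surface points).
The acceptance script uses the pinned published-scale meshes with 25
realizations for the three-layer studies and 8 for the four-layer study;
cell means are stable well below the published spreads at these counts.

## Known limitations

* **Tangential dipoles at 98% eccentricity (hybrid).** The interface flux
  of a near-cortical tangential dipole is an antisymmetric ± pair
  separated by about the dipole-to-surface distance (1.6 mm), far below
  the element scale. A constant-per-element flux with nodally lumped A/3
  transfer cannot carry this sub-element structure: feeding the FE block
  the *exact* element-mean flux still leaves a scalp RDM of ≈0.13 in that
  cell, and the full hybrid sits near 0.19, concentrated entirely in the
  polar cap. Linear flux elements would be required, but cannot be coupled
  within this scheme's element-mean matching (and discontinuous-linear
  elements cannot be coupled at all). All other cells — radial dipoles at
  every eccentricity, tangential up to 90% — are unaffected.
* BEM regions must be homogeneous and isotropic; anisotropy lives in FE
  regions only (skull radial anisotropy; general tensors are accepted by
  the FEM assembly).
* The analytic reference requires concentric shells and on-axis dipoles;
  for arbitrary meshes the reference is a uniformly refined PI-FEM solve
  (`reference_by_refinement`), with midpoints optionally snapped back to
  known spherical interfaces.
* The synthetic sphere meshes emulate the published benchmark geometry,
  not real heads: no tissue boundary noise, no segmentation error, exact
  nested topology. Passing the validation suite demonstrates solver
  correctness and the relative merits of the couplings on smooth layered
  geometry; it does not bound errors on MRI-derived meshes, which users
  supply through the labeled-mesh reader.
* Multiple disjoint BE regions and hexahedral/adaptive meshes are out of
  scope.
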