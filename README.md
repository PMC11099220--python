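# eegfwd

Solvers for the EEG forward problem — computing the electric potential on
the scalp generated by a current dipole inside a multilayer conductor head
model — with a one-shot **hybrid boundary-element / finite-element (BE–FE)
coupling** as the centerpiece, validated against semi-analytic
multilayer-sphere solutions under randomized tissue conductivities.

Intended users: researchers in EEG source analysis and bioelectromagnetic
modeling who need forward solutions on layered head models (spherical
benchmarks or labeled tetrahedral meshes), and who want the classic
solvers and the hybrid coupling in one consistent, testable package.

## The problem and the methods

Under the quasi-static approximation the potential φ obeys

    ∇·(σ∇φ) = ∇·J_P   in the head,      σ ∂φ/∂n = 0   on the scalp,

with J_P the primary current of a dipole (moment **M**, position r₀) and σ
the tissue conductivity tensor. Three discretizations are implemented:

* **BEM** — constant collocation boundary elements on the tissue
  interfaces of nested piecewise-homogeneous isotropic regions.  Element
  influence integrals of the Laplace fundamental solution
  Φ(x;ξ) = −1/(4π|x−ξ|) and its normal derivative are evaluated with exact
  flat-triangle formulas; the multi-region system couples the shells via
  continuity of potential and normal current density.
* **PI-FEM** — linear tetrahedral finite elements with per-element
  symmetric conductivity tensors (supporting a radially anisotropic
  skull, σ_r ≠ σ_t) and the partial-integration dipole load
  b_i = ∇N_i·**M**, exact for P1 elements and free of the source
  singularity.
* **Hybrid BE–FE** — the brain (homogeneous, isotropic, containing the
  dipoles) is a BE region; the remaining shells (possibly anisotropic) are
  FE.  On the shared interface each constant BE element potential equals
  the mean of its triangle's three FE nodal potentials, and the FE weak
  form receives the BE flux through exact A/3 surface integrals.  The
  coupled block system is solved directly in one step — no iteration
  between domains.

Accuracy is scored against a semi-analytic solution for a dipole inside L
concentric shells with per-layer radial/tangential conductivities, using
the standard criteria

    RDM = ‖φ_ana/‖φ_ana‖ − φ_num/‖φ_num‖‖   (0 perfect, 2 worst)
    MAG = ‖φ_num‖/‖φ_ana‖                    (1 perfect)

after average-referencing.  Monte-Carlo sweeps redraw the layer
conductivities uniformly from published tissue intervals and compare
methods pairwise with the Wilcoxon signed-rank test.

## Worked example

```sh
python examples/01_forward_solution_three_layer.py
```

prints (mesh: brain/skull/scalp shells of outer radii 8.0/8.6/9.2 cm,
interval-midpoint conductivities, unit radial dipole at 50% eccentricity,
hybrid solve):

```
mesh: 3653 nodes, 18220 tets
conductivities: [0.445  0.0173 0.575 ] S/m
scalp potentials at 913 nodes, peak-to-peak 1.421e+02 V per A*m
RDM = 0.0028 (0 is perfect), MAG = 1.0078 (1 is perfect) against the analytic multilayer-sphere solution
```

i.e. the hybrid solution reproduces the analytic scalp topography to a
relative difference of 0.3% and its amplitude to 0.8%.  The other
examples cover a Monte-Carlo method comparison (`02`), the anisotropic
four-layer analytic reference (`03`), and mesh I/O plus solving on a
user-supplied labeled mesh with a refined-FEM reference (`04`).

A thin CLI wraps the same library calls:

```sh
eegfwd mesh --model three_layer --seed 1 -o head.vtu
eegfwd solve --method hybrid --ecc 50 --orient radial \
             --sigma 0.445,0.0173,0.575 -o phi.csv
eegfwd sweep --config sweep.yaml
```

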