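"""End-to-end validation sweeps on spherical head models.

A sweep draws random layer conductivities, solves the forward problem with
each requested method for every (eccentricity, orientation) cell, scores
RDM/MAG against the multilayer-sphere analytic solution, and emits a raw
realization table plus a mean +- std / signed-rank summary.  One
conductivity draw is shared across methods and dipoles within a
realization, which is what makes the paired comparison meaningful.

Three model presets mirror the spherical validation studies:
``three_layer_iso`` (brain/skull/scalp, all isotropic), ``three_layer_aniso``
(radially anisotropic skull; brain BE, skull+scalp FE for the hybrid) and
``four_layer_aniso`` (brain/CSF/skull/scalp with anisotropic skull).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analytic import AnalyticSphereModel, model_from_spec, analytic_potential
from .bem import MultiRegionBEM
from .fem import FEMOperator
from .geometry import (LabeledTetMesh, MeshDensity, SphereModelSpec,
                       build_sphere_mesh, extract_interfaces, four_layer_model,
                       place_dipole, three_layer_model)
from .hybrid import HybridOperator
from .metrics import compare, sample_conductivities, summarize
from .solution import ForwardSolution

DEFAULT_ECCENTRICITIES = (50.0, 60.0, 70.0, 80.0, 90.0, 98.0)
DEFAULT_ORIENTATIONS = ("radial", "tangential")

MODELS = {
    "three_layer_iso": dict(spec=three_layer_model, anisotropic_skull=False),
    "three_layer_aniso": dict(spec=three_layer_model, anisotropic_skull=True),
    "four_layer_aniso": dict(spec=four_layer_model, anisotropic_skull=True),
}

# Per-method mesh densities pinned near the printed element counts of the
# validation studies (BEM total surface triangles ~3k; FEM ~34k / ~82k tets;
# hybrid FE part ~11k / ~32k tets with ~1.9k / ~3.6k interface triangles).
METHOD_DENSITIES = {
    ("three_layer", "fem"): MeshDensity(
        n_surface=1050, inner_layers=5, outer_layers=(1, 1),
        inner_grading=0.8, cap_fraction=0.25),
    ("three_layer", "hybrid"): MeshDensity(
        n_surface=949, inner_layers=2, outer_layers=(1, 1),
        cap_fraction=0.25),
    ("three_layer", "bem"): MeshDensity(
        n_surface=519, inner_layers=2, outer_layers=(1, 1),
        cap_fraction=0.25),
    ("four_layer", "fem"): MeshDensity(
        n_surface=1777, inner_layers=5, outer_layers=(1, 1, 1),
        inner_grading=0.8, cap_fraction=0.25),
    ("four_layer", "hybrid"): MeshDensity(
        n_surface=1777, inner_layers=2, outer_layers=(1, 1, 1),
        cap_fraction=0.25),
}


@dataclass
class ExperimentConfig:
    model: str = "three_layer_iso"
    methods: tuple[str, ...] = ("fem", "bem", "hybrid")
    eccentricities: tuple[float, ...] = DEFAULT_ECCENTRICITIES
    orientations: tuple[str, ...] = DEFAULT_ORIENTATIONS
    n_realizations: int = 50
    seed: int = 0
    mesh_seed: int = 1
    densities: dict = field(default_factory=dict)   # method -> MeshDensity
    output_dir: str | None = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; "
                             f"choose from {sorted(MODELS)}")
        for e in self.eccentricities:
            if not 0 <= e <= 98:
                raise ValueError("eccentricities must lie in [0, 98]")
        bad = set(self.methods) - {"fem", "bem", "hybrid"}
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}")
        if self.model != "three_layer_iso" and "bem" in self.methods:
            raise ValueError(
                "the BEM requires isotropic homogeneous regions; drop it "
                "from anisotropic models")


def _family(model: str) -> str:
    return "four_layer" if model.startswith("four") else "three_layer"


def build_solvers(config: ExperimentConfig):
    """Meshes and cached operators for every requested method."""
    info = MODELS[config.model]
    spec: SphereModelSpec = info["spec"]()
    aniso = info["anisotropic_skull"]
    solvers = {}
    for method in config.methods:
        dens = config.densities.get(
            method, METHOD_DENSITIES[(_family(config.model), method)])
        mesh = build_sphere_mesh(spec, density=dens, seed=config.mesh_seed)
        if method == "fem":
            solvers[method] = FEMOperator(mesh, spec, anisotropic_skull=aniso)
        elif method == "hybrid":
            solvers[method] = HybridOperator(mesh, spec, anisotropic_skull=aniso)
        elif method == "bem":
            solvers[method] = MultiRegionBEM(extract_interfaces(mesh))
    return spec, aniso, solvers


def run_example(config: ExperimentConfig, progress: bool = False
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run a full sweep; returns (realization table, summary table).

    With ``output_dir`` set, a per-realization checkpoint CSV is appended
    so interrupted sweeps resume where they stopped.
    """
    spec, aniso, solvers = build_solvers(config)
    draws = sample_conductivities(spec, config.n_realizations, config.seed)
    dipoles = {
        (e, o): place_dipole(spec, e, o)
        for e in config.eccentricities for o in config.orientations}

    out_dir = Path(config.output_dir) if config.output_dir else None
    ckpt = out_dir / f"{config.model}_raw.csv" if out_dir else None
    done = set()
    old = None
    if ckpt is not None and ckpt.exists():
        old = pd.read_csv(ckpt)
        done = set(old["realization"].unique())

    records = []
    for r in range(config.n_realizations):
        if r in done:
            continue
        sig = draws[r]
        ana_model = model_from_spec(spec, sig, anisotropic_skull=aniso)
        ana_cache: dict = {}
        t0 = time.time()
        for method, op in solvers.items():
            try:
                fact = op.factorize(sig)
            except Exception as exc:     # keep the sweep alive per cell
                for (e, o) in dipoles:
                    records.append(_fail_row(config, r, e, o, method, exc))
                continue
            for (e, o), dip in dipoles.items():
                try:
                    sol = fact.solve(dip)
                    ana = _analytic_at(ana_model, dip, sol, ana_cache,
                                       (method, e, o))
                    v_rdm, v_mag = compare(ana, sol)
                    records.append(dict(
                        model=config.model, realization=r,
                        eccentricity_pct=e, orientation=o, method=method,
                        RDM=v_rdm, MAG=v_mag, seed=config.seed,
                        mesh_seed=config.mesh_seed, error=""))
                except Exception as exc:
                    records.append(_fail_row(config, r, e, o, method, exc))
        if progress:
            print(f"realization {r + 1}/{config.n_realizations} "
                  f"({time.time() - t0:.1f}s)", flush=True)
        if ckpt is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            frame = pd.DataFrame(records)
            if old is not None:
                frame = pd.concat([old, frame], ignore_index=True)
            frame.to_csv(ckpt, index=False)

    table = pd.DataFrame(records)
    if old is not None:
        table = pd.concat([old, table], ignore_index=True)
    ok = table[table["error"] == ""] if "error" in table else table
    summary = summarize(ok)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / f"{config.model}_raw.csv", index=False)
        summary.to_csv(out_dir / f"{config.model}_summary.csv", index=False)
    return table, summary


def _fail_row(config, r, e, o, method, exc):
    return dict(model=config.model, realization=r, eccentricity_pct=e,
                orientation=o, method=method, RDM=np.nan, MAG=np.nan,
                seed=config.seed, mesh_seed=config.mesh_seed,
                error=f"{type(exc).__name__}: {exc}")


def _analytic_at(ana_model: AnalyticSphereModel, dipole, sol: ForwardSolution,
                 cache: dict, key) -> np.ndarray:
    """Analytic potentials at the solution's own evaluation points, cached
    per (method-geometry, dipole) because each method has fixed points."""
    ck = (key[0], key[1], key[2])
    if ck not in cache:
        cache[ck] = analytic_potential(ana_model, dipole, sol.points)
    return cache[ck]


def plot_error_boxplots(table: pd.DataFrame, metric: str = "RDM",
                        out_path: str | None = None):
    """Boxplots of RDM or MAG vs eccentricity, grouped by method.

    Cosmetic companion to :func:`run_example`; requires matplotlib.
    Returns the figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    orients = sorted(table["orientation"].unique())
    methods = sorted(table["method"].unique())
    eccs = sorted(table["eccentricity_pct"].unique())
    fig, axes = plt.subplots(1, len(orients), figsize=(6 * len(orients), 4),
                             squeeze=False)
    width = 0.8 / len(methods)
    for ax, orient in zip(axes[0], orients):
        for k, m in enumerate(methods):
            data = [table[(table.method == m) & (table.orientation == orient)
                          & (table.eccentricity_pct == e)][metric].dropna()
                    for e in eccs]
            pos = np.arange(len(eccs)) + (k - (len(methods) - 1) / 2) * width
            ax.boxplot(data, positions=pos, widths=0.9 * width,
                       tick_labels=[""] * len(eccs))
        ax.set_xticks(np.arange(len(eccs)))
        ax.set_xticklabels([f"{e:.0f}%" for e in eccs])
        ax.set_xlabel("source eccentricity")
        ax.set_ylabel(metric)
        ax.set_title(orient)
        ax.legend([plt.Line2D([], [], color=f"C{k}")
                   for k in range(len(methods))], methods)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=120)
    return fig


# --------------------------------------------------------------------------
# matched computational cost calibration
# --------------------------------------------------------------------------

def calibrate_matched_cost(
    model: str = "three_layer_iso",
    methods: tuple[str, ...] = ("fem", "bem", "hybrid"),
    target_rel: float = 0.2,
    no_calibrate: bool = True,
    max_iter: int = 6,
    seed: int = 1,
) -> dict:
    """Per-method mesh densities equalizing per-solve wall-clock.

    With ``no_calibrate`` (default) the densities pinned to the printed
    element counts are returned untouched.  Otherwise the slowest method is
    taken as the anchor and each other method's surface point count is
    scaled by bisection until its measured (factorize + solve) time falls
    within ``target_rel`` of the anchor's.  Measured times are reported in
    the result.
    """
    fam = _family(model)
    densities = {m: METHOD_DENSITIES[(fam, m)] for m in methods}
    report = {m: {"density": densities[m], "time_s": None} for m in methods}
    if no_calibrate:
        return report

    def measure(method, dens):
        cfg = ExperimentConfig(model=model, methods=(method,),
                               densities={method: dens}, mesh_seed=seed)
        spec, aniso, solvers = build_solvers(cfg)
        dip = place_dipole(spec, 50, "radial")
        sig = spec.midpoint_conductivities()
        op = solvers[method]
        t0 = time.time()
        op.factorize(sig).solve(dip)
        return time.time() - t0

    times = {m: measure(m, densities[m]) for m in methods}
    anchor = max(times.values())
    for m in methods:
        lo, hi = 0.3, 3.0
        for _ in range(max_iter):
            if abs(times[m] - anchor) <= target_rel * anchor:
                break
            factor = 0.5 * (lo + hi)
            cand = densities[m].scaled(np.sqrt(anchor / max(times[m], 1e-3)))
            t = measure(m, cand)
            densities[m], times[m] = cand, t
        report[m] = {"density": densities[m], "time_s": times[m]}
    return report


# --------------------------------------------------------------------------
# user-supplied meshes
# --------------------------------------------------------------------------

def custom_mesh_run(
    mesh: LabeledTetMesh,
    conductivity,
    dipole,
    electrodes: np.ndarray,
    method: str = "fem",
    reference_refine: int = 0,
    spec: SphereModelSpec | None = None,
    anisotropic_skull: bool = False,
):
    """Forward solve on a user mesh with electrode readout.

    Potentials at arbitrary electrode positions are obtained by projecting
    each electrode to its nearest scalp node's containing surface and
    interpolating nodal potentials barycentrically (BEM is not offered
    here: user meshes are the FEM/hybrid use case).  If ``reference_refine``
    > 0, a refined-mesh PI-FEM reference solution is also returned.

    Returns (electrode potentials, ForwardSolution, reference or None).
    """
    if method == "fem":
        op = FEMOperator(mesh, spec, anisotropic_skull=anisotropic_skull)
    elif method == "hybrid":
        op = HybridOperator(mesh, spec, anisotropic_skull=anisotropic_skull)
    else:
        raise ValueError("custom meshes support 'fem' or 'hybrid'")
    if not len(mesh.labels_present):
        raise ValueError("mesh has no region labels; supply a labeled mesh")
    sol = op.solve(conductivity, dipole)
    elec = interpolate_at_electrodes(sol, np.atleast_2d(electrodes))
    ref = None
    if reference_refine > 0:
        from .analytic import reference_by_refinement
        ref = reference_by_refinement(mesh, conductivity, dipole,
                                      refine_factor=reference_refine)
    return elec, sol, ref


def interpolate_at_electrodes(sol: ForwardSolution, electrodes: np.ndarray
                              ) -> np.ndarray:
    """Nearest-scalp-point interpolation of a solution at electrode sites.

    Electrodes are matched to the closest evaluation points; values are
    inverse-distance weighted over the 3 nearest points (degenerating to
    exact nodal values when an electrode coincides with a point).
    """
    from scipy.spatial import cKDTree
    tree = cKDTree(sol.points)
    d, idx = tree.query(np.atleast_2d(electrodes), k=3)
    d = np.maximum(d, 1e-12)
    w = 1.0 / d
    w /= w.sum(axis=1, keepdims=True)
    return (sol.potentials[idx] * w).sum(axis=1)
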