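"""Error criteria, referencing, conductivity sampling and paired statistics.

Forward-solver accuracy is summarized by two classic criteria between an
analytic (reference) and a numerical scalp-potential vector:

    RDM = || phi_ana/||phi_ana|| - phi_num/||phi_num|| ||    in [0, 2],
    MAG = ||phi_num|| / ||phi_ana||                          1 is perfect.

Because every solver determines the potential only up to an additive
constant, both vectors are average-referenced before the criteria are
evaluated.  Monte-Carlo sweeps draw layer conductivities uniformly from
tissue intervals, and methods are compared across paired draws with the
Wilcoxon signed-rank test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .geometry import SphereModelSpec
from .solution import ForwardSolution

__all__ = [
    "rdm", "mag", "average_reference", "sample_conductivities",
    "paired_signed_rank", "summarize", "compare",
]


def average_reference(phi: np.ndarray) -> np.ndarray:
    """Subtract the mean (idempotent)."""
    phi = np.asarray(phi, float)
    return phi - phi.mean()


def _check_pair(phi_ana, phi_num):
    a = np.asarray(phi_ana, float)
    b = np.asarray(phi_num, float)
    if a.shape != b.shape:
        raise ValueError("potential vectors must share evaluation points")
    if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
        raise ValueError("zero potential vector")
    return a, b


def rdm(phi_ana, phi_num) -> float:
    """Relative difference measure of unit-normalized potential vectors."""
    a, b = _check_pair(phi_ana, phi_num)
    return float(np.linalg.norm(a / np.linalg.norm(a) - b / np.linalg.norm(b)))


def mag(phi_ana, phi_num) -> float:
    """Magnitude ratio ||phi_num|| / ||phi_ana||."""
    a, b = _check_pair(phi_ana, phi_num)
    return float(np.linalg.norm(b) / np.linalg.norm(a))


def compare(reference: ForwardSolution | np.ndarray,
            numerical: ForwardSolution | np.ndarray) -> tuple[float, float]:
    """(RDM, MAG) between average-referenced solutions."""
    a = reference.potentials if isinstance(reference, ForwardSolution) else reference
    b = numerical.potentials if isinstance(numerical, ForwardSolution) else numerical
    a = average_reference(a)
    b = average_reference(b)
    return rdm(a, b), mag(a, b)


def sample_conductivities(
    spec: SphereModelSpec, n: int, seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """(n, L) independent uniform draws from each layer's interval.

    When the skull is modeled as anisotropic, its fixed (sigma_r, sigma_t)
    pair is applied downstream by the solvers; the draw for that layer is
    simply unused there.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    lo = np.array([iv[0] for iv in spec.conductivity_intervals])
    hi = np.array([iv[1] for iv in spec.conductivity_intervals])
    return rng.uniform(lo, hi, size=(n, len(lo)))


def paired_signed_rank(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are discarded (the standard zero-discard convention);
    identical samples give p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.all(d == 0):
        return 1.0
    res = scipy.stats.wilcoxon(x, y, zero_method="wilcox",
                               alternative="two-sided")
    return float(res.pvalue)


def summarize(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-cell mean +- std of RDM and MAG with pairwise method p-values.

    ``table`` rows: realization, eccentricity_pct, orientation, method,
    RDM, MAG (the raw realization table of an experiment sweep).  Returns
    one row per (orientation, eccentricity, method) with columns
    rdm_mean, rdm_std, mag_mean, mag_std and, for each other method m,
    p_rdm_vs_<m> / p_mag_vs_<m> (paired over realizations), flagged
    significant at ``alpha``.
    """
    need = {"realization", "eccentricity_pct", "orientation", "method",
            "RDM", "MAG"}
    if not need <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(need)}")
    rows = []
    methods = sorted(table["method"].unique())
    for (orient, ecc), cell in table.groupby(["orientation", "eccentricity_pct"]):
        for m in methods:
            sub = cell[cell["method"] == m].sort_values("realization")
            if sub.empty:
                continue
            row = {
                "orientation": orient, "eccentricity_pct": ecc, "method": m,
                "n": len(sub),
                "rdm_mean": sub["RDM"].mean(), "rdm_std": sub["RDM"].std(ddof=1) if len(sub) > 1 else 0.0,
                "mag_mean": sub["MAG"].mean(), "mag_std": sub["MAG"].std(ddof=1) if len(sub) > 1 else 0.0,
            }
            for other in methods:
                if other == m:
                    continue
                osub = cell[cell["method"] == other].sort_values("realization")
                if len(osub) == len(sub) and len(sub) > 0:
                    p_rdm = paired_signed_rank(sub["RDM"].values, osub["RDM"].values)
                    p_mag = paired_signed_rank(sub["MAG"].values, osub["MAG"].values)
                    row[f"p_rdm_vs_{other}"] = p_rdm
                    row[f"p_mag_vs_{other}"] = p_mag
                    row[f"sig_rdm_vs_{other}"] = p_rdm < alpha
            rows.append(row)
    return pd.DataFrame(rows)
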