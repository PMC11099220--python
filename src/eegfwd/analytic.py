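"""Semi-analytical scalp potential for a dipole in a multilayer sphere.

A current dipole sits on the z-axis inside the innermost layer of L nested
concentric shells.  Each shell j has a radial conductivity sigma_r and a
tangential conductivity sigma_t (equal for isotropic tissue).  In such a
layer the quasi-static potential separates into spherical harmonics with
radial dependence r^nu, where the two exponents per degree n solve

    nu (nu + 1) = (sigma_t / sigma_r) n (n + 1),

reducing to the familiar r^n / r^-(n+1) pair in the isotropic case.  For
the on-axis unit dipole the azimuthal structure is m = 0 (radial moment,
Legendre P_n) or m = 1 (tangential moment, associated P_n^1 with a cos
azimuth factor).  The primary (infinite-medium) potential of the dipole is
expanded about the center, interface continuity of potential and of radial
current density is imposed at every shell boundary, and a zero radial
current closes the outermost surface.  The per-degree 2L-1 coefficient
systems are solved with radius-scaled bases so the recursion stays well
conditioned up to the high orders (hundreds of terms) required for dipole
eccentricities near 98%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Dipole, LabeledTetMesh, SphereModelSpec


@dataclass(frozen=True)
class AnalyticSphereModel:
    """Concentric-shell model for the series solution.

    radii: outer shell radii [m], increasing; sigma_r, sigma_t: per-layer
    radial/tangential conductivities [S/m].
    """

    radii: tuple[float, ...]
    sigma_r: tuple[float, ...]
    sigma_t: tuple[float, ...]
    n_max: int = 400
    tol: float = 1e-10

    def __post_init__(self):
        r = np.asarray(self.radii)
        if not np.all(np.diff(r) > 0):
            raise ValueError("radii must be strictly increasing")
        if len(self.sigma_r) != len(self.radii) or len(self.sigma_t) != len(self.radii):
            raise ValueError("one (sigma_r, sigma_t) pair per layer required")
        if min(self.sigma_r) <= 0 or min(self.sigma_t) <= 0:
            raise ValueError("conductivities must be positive")

    @property
    def n_layers(self) -> int:
        return len(self.radii)


def model_from_spec(
    spec: SphereModelSpec,
    conductivities: np.ndarray,
    anisotropic_skull: bool = False,
) -> AnalyticSphereModel:
    """Analytic model matching a sphere-mesh spec and a conductivity draw."""
    sig = np.asarray(conductivities, float)
    sr, st = list(sig), list(sig)
    if anisotropic_skull:
        if spec.skull_layer is None or spec.skull_anisotropy is None:
            raise ValueError("spec has no anisotropic skull definition")
        k = spec.skull_layer - 1
        sr[k], st[k] = spec.skull_anisotropy
    return AnalyticSphereModel(
        radii=tuple(spec.radii_m), sigma_r=tuple(sr), sigma_t=tuple(st))


# --------------------------------------------------------------------------
# Legendre recurrences (Condon-Shortley-free, vectorized over points)
# --------------------------------------------------------------------------

def _legendre_terms(x: np.ndarray, n_max: int, m: int):
    """Yield (n, P_n^m(x)) for n = 1..n_max; m in {0, 1}, P_1^1 = sqrt(1-x^2)."""
    if m == 0:
        pm1 = np.ones_like(x)        # P_0
        p = x.copy()                 # P_1
        yield 1, p
        for n in range(1, n_max):
            pm1, p = p, ((2 * n + 1) * x * p - n * pm1) / (n + 1)
            yield n + 1, p
    else:
        s = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
        pm1 = np.zeros_like(x)       # P_0^1
        p = s.copy()                 # P_1^1
        yield 1, p
        for n in range(1, n_max):
            # (n - m + 1) P_{n+1}^m = (2n + 1) x P_n^m - (n + m) P_{n-1}^m
            pm1, p = p, ((2 * n + 1) * x * p - (n + 1) * pm1) / n
            yield n + 1, p


def _layer_exponents(n: int, sigma_r: float, sigma_t: float) -> tuple[float, float]:
    """Roots nu of nu(nu+1) = (sigma_t/sigma_r) n(n+1); (positive, negative)."""
    q = sigma_t / sigma_r * n * (n + 1)
    root = np.sqrt(1.0 + 4.0 * q)
    return (-1.0 + root) / 2.0, (-1.0 - root) / 2.0


def _outer_layer_solution(model: AnalyticSphereModel, n: int, b: float,
                          moment: float, m: int):
    """Solve the per-degree interface system; return a callable giving the
    coefficient of P_n^m at any radius inside the outermost layer.

    The primary-source expansion for r > b (layer 1, isotropic sigma1):
        m = 0:  f_n(r) = M/(4 pi sigma1) * n * b^(n-1) * r^-(n+1)
        m = 1:  f_n(r) = M/(4 pi sigma1) * b^(n-1) * r^-(n+1)
    Full solution in layer 1 adds alpha1 * r^n; outer layers use the
    anisotropic exponent pair, with bases scaled by the layer radii.
    """
    radii = model.radii
    L = model.n_layers
    sig_r = model.sigma_r
    s1 = sig_r[0]
    amp = moment / (4.0 * np.pi * s1) * (n if m == 0 else 1.0)
    if b == 0.0 and n > 1:              # only the n = 1 term survives at the center
        return lambda r: np.zeros_like(np.asarray(r, float))

    # b^(n-1) r^-(n+1) written as (b/r)^(n-1) / r^2: all evaluations happen at
    # r >= r_1 > b, so the ratio stays below 1 and never overflows
    def f(r):
        return amp * (b / r) ** (n - 1.0) / r ** 2

    def fprime(r):
        return -(n + 1.0) * amp * (b / r) ** (n - 1.0) / r ** 3

    # unknowns: alpha_1, (alpha_j, beta_j) j=2..L  -> 2L-1
    nun = {}
    for j in range(1, L):
        nun[j] = _layer_exponents(n, sig_r[j], model.sigma_t[j])

    size = 2 * L - 1
    A = np.zeros((size, size))
    rhs = np.zeros(size)

    def col_alpha(j):        # 0-based layer j
        return 0 if j == 0 else 2 * j - 1

    def col_beta(j):
        return 2 * j

    # basis functions in layer j >= 1 (0-based): scaled to stay O(1)
    def basis(j, r):
        nu1, nu2 = nun[j]
        ra = radii[j]            # outer radius of layer j
        rb = radii[j - 1]        # inner radius
        return (r / ra) ** nu1, (r / rb) ** nu2

    def basis_prime(j, r):
        nu1, nu2 = nun[j]
        ra, rb = radii[j], radii[j - 1]
        return (nu1 / r) * (r / ra) ** nu1, (nu2 / r) * (r / rb) ** nu2

    row = 0
    if L > 1:
        # interface at r_1 (index 0): layer 0 <-> layer 1.  The layer-1
        # regular basis is (r/r_1)^n, so its value at r_1 is exactly 1.
        r0 = radii[0]
        A[row, col_alpha(0)] = 1.0
        b1, b2 = basis(1, r0)
        A[row, col_alpha(1)] = -b1
        A[row, col_beta(1)] = -b2
        rhs[row] = -f(r0)
        row += 1
        # radial current continuity
        A[row, col_alpha(0)] = s1 * n / r0          # d/dr (r/r1)^n at r1
        d1, d2 = basis_prime(1, r0)
        A[row, col_alpha(1)] = -sig_r[1] * d1
        A[row, col_beta(1)] = -sig_r[1] * d2
        rhs[row] = -s1 * fprime(r0)
        row += 1

    for j in range(1, L - 1):       # interface at radii[j]: layer j <-> j+1
        r = radii[j]
        b1, b2 = basis(j, r)
        A[row, col_alpha(j)] = b1
        A[row, col_beta(j)] = b2
        c1, c2 = basis(j + 1, r)
        A[row, col_alpha(j + 1)] = -c1
        A[row, col_beta(j + 1)] = -c2
        row += 1
        d1, d2 = basis_prime(j, r)
        A[row, col_alpha(j)] = sig_r[j] * d1
        A[row, col_beta(j)] = sig_r[j] * d2
        e1, e2 = basis_prime(j + 1, r)
        A[row, col_alpha(j + 1)] = -sig_r[j + 1] * e1
        A[row, col_beta(j + 1)] = -sig_r[j + 1] * e2
        row += 1

    # outer boundary: zero radial current at radii[-1]
    R = radii[-1]
    if L == 1:
        A[row, col_alpha(0)] = n / R
        rhs[row] = -fprime(R)
    else:
        d1, d2 = basis_prime(L - 1, R)
        A[row, col_alpha(L - 1)] = d1
        A[row, col_beta(L - 1)] = d2
    row += 1

    coef = np.linalg.solve(A, rhs)
    if L == 1:
        a0 = coef[0]
        return lambda r: f(np.asarray(r, float)) + a0 * (np.asarray(r, float) / radii[0]) ** n
    aL = coef[col_alpha(L - 1)]
    bL = coef[col_beta(L - 1)]

    def outer(r):
        b1, b2 = basis(L - 1, np.asarray(r, float))
        return aL * b1 + bL * b2

    return outer


def analytic_potential(
    model: AnalyticSphereModel,
    dipole: Dipole,
    points: np.ndarray,
) -> np.ndarray:
    """Potential [V] at points on/inside the outermost shell.

    The dipole must sit on the z-axis strictly inside the innermost layer
    with a radial (z) or tangential (x) moment, matching the on-axis
    geometry for which the clean P_n / P_n^1 split of the series holds.
    The series is truncated once the relative tail falls below ``model.tol``
    (or at ``model.n_max``, raising if that is still not converged).
    """
    pos = dipole.position
    if abs(pos[0]) > 1e-15 or abs(pos[1]) > 1e-15:
        raise ValueError("dipole must lie on the z-axis")
    b = float(pos[2])
    if not 0 <= b < model.radii[0]:
        raise ValueError("dipole must lie strictly inside the innermost layer")
    direction = dipole.direction
    if abs(abs(direction[2]) - 1) < 1e-12:
        m, moment = 0, dipole.strength * np.sign(direction[2])
    elif abs(direction[2]) < 1e-12:
        m = 1
        moment = dipole.strength
    else:
        raise ValueError("dipole moment must be radial (z) or tangential (in-plane)")

    pts = np.atleast_2d(np.asarray(points, float))
    r = np.linalg.norm(pts, axis=1)
    if np.any(r > model.radii[-1] * (1 + 1e-9)):
        raise ValueError("evaluation points must lie on or inside the outer shell")
    if model.n_layers > 1 and np.any(r < model.radii[-2] * (1 - 1e-9)):
        raise ValueError("evaluation points must lie in the outermost layer")
    cos_t = np.clip(pts[:, 2] / np.where(r > 0, r, 1.0), -1.0, 1.0)
    if m == 1:
        # azimuthal factor cos(phi) resolved along the tangential moment axis
        rho = np.sqrt(pts[:, 0] ** 2 + pts[:, 1] ** 2)
        az = np.where(rho > 0, (pts @ direction) / np.where(rho > 0, rho, 1.0), 0.0)

    phi = np.zeros(len(pts))
    scale = 0.0
    tmax = np.inf
    tail_ok = 0
    converged = False
    for n, P in _legendre_terms(cos_t, model.n_max, m):
        coef_fn = _outer_layer_solution(model, n, b, moment, m)
        term = coef_fn(r) * P
        if m == 1:
            term = term * az
        phi += term
        tmax = np.abs(term).max()
        scale = max(scale, np.abs(phi).max())
        if scale > 0 and tmax < model.tol * scale:
            tail_ok += 1
            if tail_ok >= 5:          # several quiet terms in a row: done
                converged = True
                break
        else:
            tail_ok = 0
    if not converged and scale > 0 and tmax > 1e-6 * scale:
        raise RuntimeError(
            f"series not converged at n_max={model.n_max} "
            f"(relative tail {tmax / scale:.2e}); increase n_max")
    return phi if np.asarray(points).ndim > 1 else phi[0]


# --------------------------------------------------------------------------
# refined-FEM reference (for meshes without an analytic solution)
# --------------------------------------------------------------------------

def reference_by_refinement(
    mesh: LabeledTetMesh,
    conductivity,
    dipole: Dipole,
    refine_factor: int = 1,
    snap_spheres=(),
    max_nodes: int = 2_000_000,
):
    """Reference forward solution: PI-FEM on a uniformly refined mesh.

    refine_factor counts red-refinement passes (1 = solve on the mesh as
    given).  ``snap_spheres`` forwards interface radii whose refined
    midpoints should be projected back onto the sphere.
    """
    from .fem import assemble_and_solve_fem
    from .geometry import refine_mesh

    refined = mesh
    for _ in range(refine_factor - 1):
        refined = refine_mesh(refined, snap_spheres=snap_spheres)
        if refined.n_nodes > max_nodes:
            raise MemoryError(
                f"refined mesh exceeds {max_nodes} nodes; lower refine_factor")
    sol = assemble_and_solve_fem(refined, conductivity, dipole)
    sol.meta["reference"] = {"refine_factor": refine_factor,
                             "n_nodes": refined.n_nodes}
    return sol
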