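"""Constant-element collocation BEM for nested piecewise-homogeneous regions.

Potential and normal derivative are approximated as constants per surface
triangle and collocated at triangle centroids.  The fundamental solution of
the 3-D Laplacian used throughout is

    Phi3D(x; xi) = -1 / (4 pi |x - xi|),

so the element influence integrals are

    D1 = integral of Phi3D over the element,
    D2 = integral of d(Phi3D)/dn over the element = (solid angle) / (4 pi).

Both are evaluated with exact closed-form expressions for flat triangles
(the signed-solid-angle formula for D2, the classic edge-decomposition of
the 1/R potential integral for D1), which remain valid arbitrarily close to
the element, so no special near-singular quadrature is needed.  The
self-element D2 is identically zero (the field point lies in the element
plane).

The multi-region assembly follows the nested-shell picture: the innermost
region carries the dipole (Poisson equation, volume term reduces to the
two-monopole / point-dipole source term), outer shells satisfy the Laplace
equation, and interface continuity of potential and normal current density
merges the per-region systems into one square linear system, closed by the
no-flux condition at the scalp/air boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .geometry import Dipole, InterfaceSurface
from .solution import ForwardSolution


# --------------------------------------------------------------------------
# kernels: exact flat-triangle integrals
# --------------------------------------------------------------------------

def triangle_solid_angles(verts: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Signed solid angles of triangles seen from observation points.

    verts: (t, 3, 3) triangle vertices; obs: (3,) or (o, 3).
    Returns (t,) or (o, t).  The sign is positive when the triangle's
    normal (right-hand rule on the vertex order) points away from the
    observer, i.e. sum over an outward-oriented closed surface = 4 pi for
    interior points.
    """
    obs = np.asarray(obs, float)
    single = obs.ndim == 1
    obs2 = obs[None] if single else obs
    R = verts[None, :, :, :] - obs2[:, None, None, :]     # (o, t, 3, 3)
    r = np.linalg.norm(R, axis=3)                          # (o, t, 3)
    R1, R2, R3 = R[:, :, 0], R[:, :, 1], R[:, :, 2]
    num = np.einsum("otk,otk->ot", R1, np.cross(R2, R3))
    den = (r[:, :, 0] * r[:, :, 1] * r[:, :, 2]
           + np.einsum("otk,otk->ot", R1, R2) * r[:, :, 2]
           + np.einsum("otk,otk->ot", R1, R3) * r[:, :, 1]
           + np.einsum("otk,otk->ot", R2, R3) * r[:, :, 0])
    omega = 2.0 * np.arctan2(num, den)
    return omega[0] if single else omega


def triangle_inv_r_integrals(verts: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Exact integral of 1/|x - xi| over flat triangles.

    verts: (t, 3, 3); obs: (3,) or (o, 3); returns (t,) or (o, t).
    Edge-decomposition formula (per-edge log terms plus the projected
    solid-angle correction), valid for any field point not exactly on a
    triangle edge.
    """
    obs = np.asarray(obs, float)
    single = obs.ndim == 1
    obs2 = obs[None] if single else obs           # (o, 3)

    v = verts                                      # (t, 3, 3)
    e = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    nhat = e / np.linalg.norm(e, axis=1, keepdims=True)       # (t, 3)

    d = np.einsum("tk,otk->ot", nhat, obs2[:, None, :] - v[None, :, 0, :])
    rho = obs2[:, None, :] - d[:, :, None] * nhat[None, :, :]  # (o, t, 3) projection

    total = np.zeros(d.shape)
    absd = np.abs(d)
    for i in range(3):
        a = v[:, i]                    # (t, 3)
        b = v[:, (i + 1) % 3]
        ell = b - a
        ell_len = np.linalg.norm(ell, axis=1, keepdims=True)
        shat = ell / ell_len
        mhat = np.cross(shat, nhat)    # in-plane outward edge normal
        am = a[None, :, :] - rho       # (o, t, 3)
        bm = b[None, :, :] - rho
        lm = np.einsum("otk,tk->ot", am, shat)
        lp = np.einsum("otk,tk->ot", bm, shat)
        t0 = np.einsum("otk,tk->ot", am, mhat)
        Rm = np.sqrt(lm ** 2 + t0 ** 2 + d ** 2)
        Rp = np.sqrt(lp ** 2 + t0 ** 2 + d ** 2)
        R02 = t0 ** 2 + d ** 2
        # log term; guard the degenerate on-edge-line case (t0 = d = 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_term = np.log(Rp + lp) - np.log(Rm + lm)
            atan_term = (np.arctan2(t0 * lp, R02 + absd * Rp)
                         - np.arctan2(t0 * lm, R02 + absd * Rm))
        log_term = np.where(np.abs(t0) + absd < 1e-14, 0.0, log_term)
        total += t0 * log_term - absd * atan_term
    out = total
    return out[0] if single else out


def dipole_source_element_means(
    surface: InterfaceSurface,
    dipole: Dipole,
    sigma1: float,
    step: float = 1e-7,
) -> np.ndarray:
    """Element means of the dipole source term over each surface triangle.

    The collocation unknowns are element *means*, and for dipoles close to
    the surface the point-sampled source term aliases the near-field peak so
    badly that the discrete compatibility condition (the analogue of zero
    net injected current) is violated by tens of percent.  Averaging the
    source term over each element restores it.  The average is

        (1/A_T) dS-integral of  -(1/(4 pi sigma)) M.(xi-r0)/|xi-r0|^3
            = -(1/(4 pi sigma A_T)) M . grad_r0 (dS-integral of 1/|xi-r0|)

    and the inner integral is the exact flat-triangle 1/R formula, so a
    central difference in r0 gives near-machine accuracy.
    """
    verts = surface.vertices
    areas = surface.areas()
    grad = np.empty((3, verts.shape[0]))
    for k in range(3):
        e = np.zeros(3)
        e[k] = step
        ip = triangle_inv_r_integrals(verts, dipole.position + e)
        im = triangle_inv_r_integrals(verts, dipole.position - e)
        grad[k] = (ip - im) / (2.0 * step)
    return -(dipole.moment @ grad) / (4.0 * np.pi * sigma1 * areas)


def d1_d2_matrices(
    surface: InterfaceSurface,
    obs: np.ndarray,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Influence matrices D1, D2 of shape (n_obs, n_elements).

    D2 uses the surface's stored outward orientation.  Observation points
    exactly at an element's own centroid must be handled by the caller
    (self solid angle is set to zero during assembly).
    """
    verts = surface.vertices
    obs = np.atleast_2d(np.asarray(obs, float))
    D1 = np.empty((obs.shape[0], verts.shape[0]))
    D2 = np.empty_like(D1)
    for s in range(0, obs.shape[0], chunk):
        sl = slice(s, min(s + chunk, obs.shape[0]))
        D1[sl] = -triangle_inv_r_integrals(verts, obs[sl]) / (4.0 * np.pi)
        D2[sl] = triangle_solid_angles(verts, obs[sl]) / (4.0 * np.pi)
    return D1, D2


def element_integrals_D1_D2(
    surface: InterfaceSurface, collocation: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element D1, D2 for a single collocation point (vectors of length
    n_elements)."""
    D1, D2 = d1_d2_matrices(surface, np.asarray(collocation, float)[None])
    return D1[0], D2[0]


# --------------------------------------------------------------------------
# dipole source term
# --------------------------------------------------------------------------

def dipole_source_term(
    dipole: Dipole,
    sigma1: float,
    collocation: np.ndarray,
    form: str = "limit",
    separation: float = 1e-6,
    exclusion: float = 1e-9,
) -> np.ndarray:
    """Volume source term of the innermost-region boundary integral equation.

    ``limit`` (default): point-dipole limit
        -(1/(4 pi sigma1)) M . (xi - r0) / |xi - r0|^3
    ``monopole``: explicit source/sink pair
        (I/sigma1) [Phi3D(xi; r2) - Phi3D(xi; r1)]
    """
    xi = np.atleast_2d(np.asarray(collocation, float))
    if form == "limit":
        diff = xi - dipole.position
        r = np.linalg.norm(diff, axis=1)
        if np.any(r < exclusion):
            raise ValueError("collocation point inside the dipole exclusion ball")
        out = -(diff @ dipole.moment) / (4.0 * np.pi * sigma1 * r ** 3)
    elif form == "monopole":
        r1, r2, I = dipole.monopoles(separation)
        d1 = np.linalg.norm(xi - r1, axis=1)
        d2 = np.linalg.norm(xi - r2, axis=1)
        if np.any(d1 < exclusion) or np.any(d2 < exclusion):
            raise ValueError("collocation point inside the dipole exclusion ball")
        out = (I / sigma1) * (-1.0 / (4.0 * np.pi * d2) + 1.0 / (4.0 * np.pi * d1))
    else:
        raise ValueError("form must be 'limit' or 'monopole'")
    return out if np.asarray(collocation).ndim > 1 else out[0]


# --------------------------------------------------------------------------
# multi-region assembly
# --------------------------------------------------------------------------

@dataclass
class BEMSystem:
    """Assembled dense collocation system A_BE X_BE = B_BE.

    Unknown layout: mean potentials phi-bar per element of every interface
    (inner to outer), followed by mean normal derivatives p-bar per element
    of every *internal* interface (the scalp/air flux is identically zero
    and eliminated).  The system retains the pure-Neumann constant null
    space; :func:`solve_bem` removes it by deflation.
    """

    A: np.ndarray
    B: np.ndarray
    phi_offsets: list[int]
    p_offsets: list[int]
    surfaces: list[InterfaceSurface]
    conductivities: np.ndarray
    dipole: Dipole
    meta: dict = field(default_factory=dict)

    @property
    def n_unknowns(self) -> int:
        return self.A.shape[1]


class MultiRegionBEM:
    """Collocation BEM on a fixed set of nested interfaces.

    Geometry-dependent influence blocks are computed once; reassembling for
    new conductivities or dipoles reuses them (conductivity enters only
    through interface flux scaling and the source term).
    """

    def __init__(self, surfaces: list[InterfaceSurface]):
        if not surfaces:
            raise ValueError("at least one interface required")
        self._check_nested(surfaces)
        self.surfaces = surfaces
        self.L = len(surfaces)
        self.N = [s.n_triangles for s in surfaces]
        self.centroids = [s.centroids() for s in surfaces]
        # influence blocks D1[(c, j)], D2[(c, j)] with collocation on surface
        # c against elements of surface j (stored outward normals); only the
        # pairs that share a region are needed.
        self.D1: dict[tuple[int, int], np.ndarray] = {}
        self.D2: dict[tuple[int, int], np.ndarray] = {}
        pairs = {(0, 0)}
        for j in range(1, self.L):
            pairs |= {(j - 1, j - 1), (j - 1, j), (j, j - 1), (j, j)}
        for c, j in sorted(pairs):
            D1, D2 = d1_d2_matrices(surfaces[j], self.centroids[c])
            if c == j:
                np.fill_diagonal(D2, 0.0)   # flat-triangle self term
            self.D1[(c, j)] = D1
            self.D2[(c, j)] = D2

        self.n_phi = sum(self.N)
        self.n_p = sum(self.N[:-1])
        self.phi_offsets = list(np.cumsum([0] + self.N[:-1]))
        self.p_offsets = [self.n_phi + o for o in np.cumsum([0] + self.N[:-2])]

    def factorize(self, conductivities, source_form: str = "element_mean"
                  ) -> BEMFactorization:
        """Factorize once per conductivity draw; solve many dipoles cheaply."""
        return BEMFactorization(self, conductivities, source_form)

    @staticmethod
    def _check_nested(surfaces: list[InterfaceSurface]) -> None:
        radius = [np.linalg.norm(s.centroids(), axis=1).max() for s in surfaces]
        if not all(radius[i] < radius[i + 1] for i in range(len(surfaces) - 1)):
            raise ValueError("interfaces must be strictly nested (inner to outer)")

    def assemble(self, conductivities: np.ndarray, dipole: Dipole,
                 source_form: str = "element_mean") -> BEMSystem:
        sig = np.asarray(conductivities, float)
        if sig.shape != (self.L,):
            raise ValueError(f"need {self.L} region conductivities")
        r_dip = np.linalg.norm(dipole.position)
        r1 = np.linalg.norm(self.centroids[0], axis=1).min()
        if r_dip >= r1:
            raise ValueError("dipole must lie strictly inside the innermost region")

        n = self.n_phi + self.n_p
        A = np.zeros((n, n))
        B = np.zeros(n)
        row = 0

        def phi_cols(j):
            return slice(self.phi_offsets[j], self.phi_offsets[j] + self.N[j])

        def p_cols(j):
            return slice(self.p_offsets[j], self.p_offsets[j] + self.N[j])

        # region 1 (innermost, contains the dipole): boundary = surface 0
        rows = slice(row, row + self.N[0])
        A[rows, phi_cols(0)] = -self.D2[(0, 0)]
        A[rows, phi_cols(0)] += 0.5 * np.eye(self.N[0])
        if self.L > 1:      # on the scalp/air boundary the flux is known zero
            A[rows, p_cols(0)] = self.D1[(0, 0)]
        # Sign convention: the two-monopole labeling behind
        # dipole_source_term places the current *source* so that the term
        # carries the negated potential of the standard dipole
        # phi = M.(r-r0)/(4 pi sigma |r-r0|^3).  The solvers in this package
        # (and the analytic reference) all use the standard convention, so
        # the source term enters the right-hand side negated.
        if source_form == "element_mean":
            B[rows] = -dipole_source_element_means(
                self.surfaces[0], dipole, sig[0])
        else:
            B[rows] = -dipole_source_term(dipole, sig[0], self.centroids[0],
                                          form=source_form)
        row += self.N[0]

        # regions 2..L: Laplace, boundaries = surfaces j-1 (inner) and j (outer)
        for reg in range(1, self.L):        # region index reg+1, 0-based reg
            inner, outer = reg - 1, reg
            ratio = sig[reg - 1] / sig[reg]     # flux continuity across inner iface
            for c in (inner, outer):
                rows = slice(row, row + self.N[c])
                # outer boundary of the region: stored normal is region-outward
                A[rows, phi_cols(outer)] = -self.D2[(c, outer)]
                if outer < self.L - 1:
                    A[rows, p_cols(outer)] = self.D1[(c, outer)]
                # inner boundary: region-outward normal is the flipped stored one
                A[rows, phi_cols(inner)] = self.D2[(c, inner)]
                A[rows, p_cols(inner)] = -ratio * self.D1[(c, inner)]
                # collocation point sits on surface c: add the 1/2 phi term
                A[rows, phi_cols(c)] += 0.5 * np.eye(self.N[c])
                row += self.N[c]

        return BEMSystem(
            A=A, B=B,
            phi_offsets=self.phi_offsets + [self.n_phi],
            p_offsets=self.p_offsets + [self.n_phi + self.n_p],
            surfaces=self.surfaces,
            conductivities=sig,
            dipole=dipole,
            meta={"source_form": source_form},
        )


class BEMFactorization:
    """LU-factorized BEM system for one conductivity draw.

    The coefficient matrix is dipole-independent, so Monte-Carlo sweeps
    factorize once per draw and back-substitute per dipole.
    """

    def __init__(self, operator: "MultiRegionBEM", conductivities,
                 source_form: str = "element_mean"):
        self.op = operator
        self.sig = np.asarray(conductivities, float)
        self.source_form = source_form
        # dummy dipole well inside region 1 only to assemble the matrix
        r1 = np.linalg.norm(operator.centroids[0], axis=1).min()
        probe = Dipole(position=np.array([0.0, 0.0, 0.25 * r1]),
                       direction=np.array([0.0, 0.0, 1.0]))
        system = operator.assemble(self.sig, probe, source_form)
        self._template = system
        n = system.n_unknowns
        n_phi = system.phi_offsets[-1]
        A_aug = np.zeros((n + 1, n + 1))
        A_aug[:n, :n] = system.A
        A_aug[:n, n] = 1.0
        A_aug[n, :n_phi] = 1.0 / n_phi
        self._lu = scipy.linalg.lu_factor(A_aug)
        self._n = n

    def solve(self, dipole: Dipole) -> ForwardSolution:
        op, sig = self.op, self.sig
        rows = slice(0, op.N[0])
        B = np.zeros(self._n + 1)
        if self.source_form == "element_mean":
            B[rows] = -dipole_source_element_means(op.surfaces[0], dipole, sig[0])
        else:
            B[rows] = -dipole_source_term(dipole, sig[0], op.centroids[0],
                                          form=self.source_form)
        x = scipy.linalg.lu_solve(self._lu, B)
        X = x[:self._n]
        scalp = op.surfaces[-1]
        lo = self._template.phi_offsets[len(op.surfaces) - 1]
        phi_scalp = X[lo:lo + scalp.n_triangles]
        phi_scalp = phi_scalp - phi_scalp.mean()
        return ForwardSolution(
            points=scalp.centroids(), potentials=phi_scalp,
            referencing="average",
            meta={"method": "bem", "X": X,
                  "conductivities": sig.tolist(),
                  "dipole_position": dipole.position.tolist(),
                  "dipole_moment": dipole.moment.tolist()},
        )


def assemble_multiregion(
    surfaces: list[InterfaceSurface],
    conductivities,
    dipole: Dipole,
    source_form: str = "element_mean",
) -> BEMSystem:
    """One-shot multi-region assembly (see :class:`MultiRegionBEM` for the
    cached variant used in Monte-Carlo sweeps)."""
    return MultiRegionBEM(surfaces).assemble(
        np.asarray(conductivities, float), dipole, source_form)


def solve_bem(system: BEMSystem, cond_warn: float = 1e12) -> ForwardSolution:
    """Direct dense solve with deflation of the constant null space.

    The all-Neumann closure leaves the potential defined up to a constant;
    the system is solved in the augmented (Lagrange) form that pins the mean
    of all element potentials to zero, and the scalp potentials are returned
    average-referenced at the scalp element centroids.
    """
    n = system.n_unknowns
    n_phi = system.phi_offsets[-1]
    A_aug = np.zeros((n + 1, n + 1))
    A_aug[:n, :n] = system.A
    A_aug[:n, n] = 1.0                    # deflation column
    A_aug[n, :n_phi] = 1.0 / n_phi        # mean-potential constraint
    b_aug = np.concatenate([system.B, [0.0]])
    x = scipy.linalg.solve(A_aug, b_aug)
    X = x[:n]

    scalp = system.surfaces[-1]
    lo = system.phi_offsets[len(system.surfaces) - 1]
    phi_scalp = X[lo:lo + scalp.n_triangles]
    phi_scalp = phi_scalp - phi_scalp.mean()
    return ForwardSolution(
        points=scalp.centroids(),
        potentials=phi_scalp,
        referencing="average",
        meta={"method": "bem", "unknowns": n, "X": X,
              "conductivities": system.conductivities.tolist(),
              "dipole_position": system.dipole.position.tolist(),
              "dipole_moment": system.dipole.moment.tolist()},
    )
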