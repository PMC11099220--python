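"""Linear tetrahedral FEM with a partial-integration dipole source (PI-FEM).

The conduction equation div(sigma grad phi) = div(J_P) with a homogeneous
Neumann boundary is discretized with linear (P1) tetrahedra.  Conductivity
is a symmetric positive-definite 3x3 tensor per element, so radially
anisotropic shells (distinct sigma_r / sigma_t, e.g. the skull) are
expressed exactly; isotropic tissue is sigma * I.

The dipole right-hand side uses the partial-integration form: testing
div(J_P) with a shape function and integrating by parts gives

    b_i = grad(N_i) . M        (nodes of the tetrahedron containing r0)

which is exact for P1 elements (constant gradients) and avoids the
potential's singularity at the source.  The resulting pure-Neumann system
is singular up to an additive constant; the solve pins the mean nodal
potential with a Lagrange multiplier (deflation) and verifies the residual
of the original system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Dipole, LabeledTetMesh, SphereModelSpec, TetLocator
from .solution import ForwardSolution


# --------------------------------------------------------------------------
# conductivity assignment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConductivityAssignment:
    """Per-region conductivity rules mapped to per-element tensors.

    ``isotropic``: region label -> sigma [S/m].
    ``radial_anisotropic``: region label -> (sigma_r, sigma_t); the tensor is
    sigma_r * rr^T + sigma_t * (I - rr^T) with r the element-centroid unit
    radial direction (so sigma_r = sigma_t reduces to the isotropic rule).
    """

    isotropic: dict = field(default_factory=dict)
    radial_anisotropic: dict = field(default_factory=dict)

    @classmethod
    def from_spec(cls, spec: SphereModelSpec, conductivities,
                  anisotropic_skull: bool = False) -> "ConductivityAssignment":
        sig = np.asarray(conductivities, float)
        iso = {j + 1: float(sig[j]) for j in range(spec.n_layers)}
        aniso = {}
        if anisotropic_skull:
            if spec.skull_layer is None or spec.skull_anisotropy is None:
                raise ValueError("spec has no anisotropic skull definition")
            iso.pop(spec.skull_layer)
            aniso[spec.skull_layer] = spec.skull_anisotropy
        return cls(isotropic=iso, radial_anisotropic=aniso)

    def element_tensors(self, mesh: LabeledTetMesh) -> np.ndarray:
        """(n_tets, 3, 3) SPD tensor per element."""
        out = np.zeros((mesh.n_tets, 3, 3))
        cents = mesh.tet_centroids()
        eye = np.eye(3)
        for label, sigma in self.isotropic.items():
            out[mesh.region_label == label] = sigma * eye
        for label, (sr, st) in self.radial_anisotropic.items():
            m = mesh.region_label == label
            c = cents[m]
            rhat = c / np.linalg.norm(c, axis=1, keepdims=True)
            rr = rhat[:, :, None] * rhat[:, None, :]
            out[m] = sr * rr + st * (eye - rr)
        missing = set(mesh.labels_present) - set(self.isotropic) - set(
            self.radial_anisotropic)
        if missing:
            raise ValueError(f"no conductivity rule for regions {sorted(missing)}")
        return out


# --------------------------------------------------------------------------
# element matrices and global assembly
# --------------------------------------------------------------------------

def shape_gradients(nodes4: np.ndarray) -> tuple[np.ndarray, float]:
    """Constant P1 shape-function gradients (4, 3) and volume of one tet."""
    T = (nodes4[1:] - nodes4[0]).T
    vol = np.linalg.det(T) / 6.0
    if vol <= 0:
        raise ValueError("inverted tetrahedron (non-positive volume)")
    Tinv = np.linalg.inv(T)
    g = np.vstack([-Tinv.sum(axis=0), Tinv])
    return g, vol


def element_stiffness(nodes4: np.ndarray, tensor: np.ndarray) -> np.ndarray:
    """4x4 element stiffness  K_ij = V * grad(N_i) . sigma grad(N_j)."""
    g, vol = shape_gradients(np.asarray(nodes4, float))
    return vol * g @ np.asarray(tensor, float) @ g.T


def _all_shape_gradients(mesh: LabeledTetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized gradients (m, 4, 3) and volumes (m,) for every element."""
    p = mesh.nodes[mesh.tets]
    T = np.transpose(p[:, 1:] - p[:, 0:1], (0, 2, 1))      # (m, 3, 3)
    vol = np.linalg.det(T) / 6.0
    if np.any(vol <= 0):
        bad = int(np.argmax(vol <= 0))
        raise ValueError(f"inverted tetrahedron at element {bad}")
    Tinv = np.linalg.inv(T)
    g = np.empty((mesh.n_tets, 4, 3))
    g[:, 1:] = Tinv                      # grad(lambda_i) = i-th row of T^-1
    g[:, 0] = -g[:, 1:].sum(axis=1)
    return g, vol


def assemble_stiffness(mesh: LabeledTetMesh, tensors: np.ndarray) -> sp.csr_array:
    """Global sparse stiffness for per-element conductivity tensors."""
    g, vol = _all_shape_gradients(mesh)
    Ke = np.einsum("m,mik,mkl,mjl->mij", vol, g, tensors, g)
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    K = sp.coo_array((Ke.ravel(), (rows, cols)),
                     shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
    return K


@dataclass
class FEMSystem:
    """Sparse PI-FEM system  K_FE phi_FE = B_FE (pure Neumann, singular up
    to a constant; B sums to zero by construction)."""

    K: sp.csr_array
    B: np.ndarray
    mesh: LabeledTetMesh
    meta: dict = field(default_factory=dict)


def pi_load(
    dipole: Dipole,
    mesh: LabeledTetMesh,
    locator: TetLocator | None = None,
    form: str = "point",
    separation: float = 1e-6,
) -> np.ndarray:
    """Partial-integration load vector (length n_nodes, zero-sum).

    ``point``: b_i = grad(N_i) . M on the host tet of the dipole position.
    ``monopole``: b_i = I * [N_i(r2) - N_i(r1)] over the host tets of the
    two monopole positions (converges to ``point`` as the separation
    vanishes).
    """
    locator = locator or TetLocator(mesh)
    B = np.zeros(mesh.n_nodes)
    if form == "point":
        t, _ = locator.find(dipole.position)
        g, _vol = shape_gradients(mesh.nodes[mesh.tets[t]])
        B[mesh.tets[t]] = g @ dipole.moment
    elif form == "monopole":
        r1, r2, current = dipole.monopoles(separation)
        for pos, sign in ((r2, 1.0), (r1, -1.0)):
            t, lam = locator.find(pos)
            B[mesh.tets[t]] += sign * current * lam
    else:
        raise ValueError("form must be 'point' or 'monopole'")
    return B


def solve_neumann(K: sp.csr_array, B: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Solve the singular pure-Neumann system with a mean-zero constraint.

    Augmented (Lagrange) sparse direct solve; raises if the residual of the
    original system exceeds ``tol`` relative to ||B||.
    """
    n = K.shape[0]
    ones = np.ones((n, 1)) / n
    K_aug = sp.bmat([[K, sp.csr_array(ones)],
                     [sp.csr_array(ones.T), None]], format="csc")
    x = spla.spsolve(K_aug, np.concatenate([B, [0.0]]))
    phi = x[:n]
    bnorm = np.linalg.norm(B)
    if bnorm > 0:
        res = np.linalg.norm(K @ phi - B) / bnorm
        if res > tol:
            raise RuntimeError(f"Neumann solve residual {res:.2e} exceeds {tol:.0e}")
    return phi


class FEMOperator:
    """PI-FEM on a fixed mesh with cached per-region stiffness structure.

    Monte-Carlo conductivity draws only rescale the cached per-region
    unit-conductivity stiffness matrices, so reassembly is cheap; the
    anisotropic-skull contribution (fixed tensor) is cached once.
    """

    def __init__(self, mesh: LabeledTetMesh, spec: SphereModelSpec | None = None,
                 anisotropic_skull: bool = False):
        self.mesh = mesh
        self.spec = spec
        self.anisotropic_skull = anisotropic_skull
        self.locator = TetLocator(mesh)
        self.labels = [int(l) for l in mesh.labels_present]
        eye = np.eye(3)
        self._unit_K: dict[int, sp.csr_array] = {}
        self._fixed_K: sp.csr_array | None = None
        skull = spec.skull_layer if (spec is not None and anisotropic_skull) else None
        for label in self.labels:
            mask = mesh.region_label == label
            sub = _masked_stiffness(mesh, mask, eye[None].repeat(mask.sum(), 0))
            if label == skull:
                assign = ConductivityAssignment(
                    radial_anisotropic={label: spec.skull_anisotropy},
                    isotropic={l: 0.0 for l in self.labels if l != label})
                self._fixed_K = assemble_stiffness(
                    mesh, assign.element_tensors(mesh))
            else:
                self._unit_K[label] = sub
        self.skull_label = skull
        self.scalp_nodes = _outer_boundary_nodes(mesh)

    def stiffness(self, conductivities) -> sp.csr_array:
        sig = np.asarray(conductivities, float)
        K = self._fixed_K.copy() if self._fixed_K is not None else None
        for label in self.labels:
            if label == self.skull_label:
                continue
            term = sig[label - 1] * self._unit_K[label]
            K = term if K is None else K + term
        return K

    def factorize(self, conductivities, tol: float = 1e-10) -> "FEMFactorization":
        """Factorize the stiffness once per conductivity draw."""
        return FEMFactorization(self, conductivities, tol)

    def solve(self, conductivities, dipole: Dipole, tol: float = 1e-10
              ) -> ForwardSolution:
        K = self.stiffness(conductivities)
        B = pi_load(dipole, self.mesh, self.locator)
        phi = solve_neumann(K, B, tol=tol)
        scalp = self.scalp_nodes
        pots = phi[scalp] - phi[scalp].mean()
        return ForwardSolution(
            points=self.mesh.nodes[scalp],
            potentials=pots,
            referencing="average",
            meta={"method": "fem", "n_nodes": self.mesh.n_nodes,
                  "nodal_potentials": phi,
                  "conductivities": np.asarray(conductivities, float).tolist(),
                  "anisotropic_skull": self.anisotropic_skull,
                  "dipole_position": dipole.position.tolist(),
                  "dipole_moment": dipole.moment.tolist()},
        )


class FEMFactorization:
    """Sparse factorization of one conductivity draw's deflated stiffness."""

    def __init__(self, operator: FEMOperator, conductivities, tol: float = 1e-10):
        self.op = operator
        self.sig = np.asarray(conductivities, float)
        self.tol = tol
        self.K = operator.stiffness(self.sig)
        n = self.K.shape[0]
        ones = np.ones((n, 1)) / n
        K_aug = sp.bmat([[self.K, sp.csr_array(ones)],
                         [sp.csr_array(ones.T), None]], format="csc")
        self._lu = spla.splu(K_aug)
        self._n = n

    def solve(self, dipole: Dipole) -> ForwardSolution:
        op = self.op
        B = pi_load(dipole, op.mesh, op.locator)
        x = self._lu.solve(np.concatenate([B, [0.0]]))
        phi = x[:self._n]
        res = np.linalg.norm(self.K @ phi - B) / np.linalg.norm(B)
        if res > self.tol:
            raise RuntimeError(f"Neumann solve residual {res:.2e}")
        scalp = op.scalp_nodes
        pots = phi[scalp] - phi[scalp].mean()
        return ForwardSolution(
            points=op.mesh.nodes[scalp], potentials=pots,
            referencing="average",
            meta={"method": "fem", "nodal_potentials": phi,
                  "conductivities": self.sig.tolist(),
                  "anisotropic_skull": op.anisotropic_skull,
                  "dipole_position": dipole.position.tolist(),
                  "dipole_moment": dipole.moment.tolist()},
        )


def _masked_stiffness(mesh: LabeledTetMesh, mask: np.ndarray,
                      tensors_sub: np.ndarray) -> sp.csr_array:
    sub = LabeledTetMesh(nodes=mesh.nodes, tets=mesh.tets[mask],
                         region_label=mesh.region_label[mask])
    return assemble_stiffness(sub, tensors_sub)


def _outer_boundary_nodes(mesh: LabeledTetMesh) -> np.ndarray:
    """Sorted node indices on the outer (scalp) boundary surface."""
    tets = mesh.tets
    faces = np.sort(np.vstack([
        tets[:, [1, 2, 3]], tets[:, [0, 3, 2]],
        tets[:, [0, 1, 3]], tets[:, [0, 2, 1]]]), axis=1)
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    return np.unique(uniq[counts == 1])


def assemble_and_solve_fem(
    mesh: LabeledTetMesh,
    conductivity,
    dipole: Dipole,
    tol: float = 1e-10,
) -> ForwardSolution:
    """One-shot PI-FEM solve.

    ``conductivity`` may be a :class:`ConductivityAssignment` or an array of
    per-region isotropic values (region 1..L).
    """
    if isinstance(conductivity, ConductivityAssignment):
        tensors = conductivity.element_tensors(mesh)
        K = assemble_stiffness(mesh, tensors)
    else:
        sig = np.asarray(conductivity, float)
        assign = ConductivityAssignment(
            isotropic={int(l): float(sig[int(l) - 1]) for l in mesh.labels_present})
        K = assemble_stiffness(mesh, assign.element_tensors(mesh))
    B = pi_load(dipole, mesh)
    phi = solve_neumann(K, B, tol=tol)
    scalp = _outer_boundary_nodes(mesh)
    pots = phi[scalp] - phi[scalp].mean()
    return ForwardSolution(
        points=mesh.nodes[scalp], potentials=pots, referencing="average",
        meta={"method": "fem", "n_nodes": mesh.n_nodes,
              "nodal_potentials": phi,
              "dipole_position": dipole.position.tolist(),
              "dipole_moment": dipole.moment.tolist()},
    )
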