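"""One-shot hybrid BE-FE coupling for the EEG forward problem.

The head is split by method: the homogeneous isotropic region containing
the dipoles (the brain) is handled by the boundary element method, all
remaining shells (possibly anisotropic, e.g. the skull) by linear
tetrahedral finite elements.  Both discretizations share the brain-surface
triangulation: BE triangles are exactly faces of FE tetrahedra, which is
guaranteed when the surfaces are extracted from one labeled volume mesh.

Coupling conditions on the shared interface S_BE-FE:

* potential matching - a constant BE element potential equals the average
  of its triangle's three FE nodal potentials,
      phi_BE = (phi_FE1 + phi_FE2 + phi_FE3) / 3,
  applied by substitution: every occurrence of an interface phi-bar unknown
  in a BE collocation row is replaced by the 1/3-weighted FE nodal values,
  eliminating the interface potentials and keeping the system square;
* normal current continuity - the FE weak form's surface term over S_BE-FE
  is expressed through the BE flux unknowns p-bar via
      sigma_FE d(phi_FE)/dn_FE = -sigma_BE d(phi_BE)/dn_BE,
  contributing exactly -sigma_BE p-bar_T Area_T / 3 to each of triangle T's
  three nodes (the integral of a P1 shape function over a triangle).

The assembled block system couples the sparse FE stiffness with the dense
BE collocation matrix and is solved in one step - no iteration between the
domains - with the global constant null space removed by a mean-zero
deflation constraint and a Schur-complement block elimination standing in
for plain Gaussian elimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .bem import d1_d2_matrices, dipole_source_element_means, dipole_source_term
from .geometry import (Dipole, InterfaceSurface, LabeledTetMesh,
                       SphereModelSpec, extract_interfaces)
from .fem import (ConductivityAssignment, FEMOperator, _outer_boundary_nodes,
                  assemble_stiffness)
from .solution import ForwardSolution


@dataclass(frozen=True)
class RegionAssignment:
    """Method per region label: "BE" or "FE".

    The region containing the dipoles must be BE (avoids the FEM source
    singularity); anisotropic regions must be FE (BEM requires homogeneous
    isotropic regions).
    """

    method: dict

    def validate(self, labels, dipole_region: int, anisotropic_regions=()) -> None:
        for lab in labels:
            if self.method.get(int(lab)) not in ("BE", "FE"):
                raise ValueError(f"region {lab} has no BE/FE assignment")
        if self.method[dipole_region] != "BE":
            raise ValueError(
                "the region containing dipoles must be modeled with the BEM")
        for lab in anisotropic_regions:
            if self.method[int(lab)] != "FE":
                raise ValueError(
                    "regions with anisotropic conductivity must be modeled "
                    "with the FEM")

    @classmethod
    def brain_be(cls, labels) -> "RegionAssignment":
        """The configuration studied here: innermost region BE, rest FE."""
        labels = [int(l) for l in labels]
        return cls(method={l: ("BE" if l == min(labels) else "FE") for l in labels})


def couple_interface(
    surface: InterfaceSurface,
    fe_node_index: np.ndarray,
    n_fe_nodes: int,
    sigma_be: float,
) -> tuple[sp.csr_array, sp.csr_array]:
    """Sparse coupling blocks for a BE/FE interface.

    Returns (averaging A_map, flux load F):
    * ``A_map`` (n_triangles x n_fe_nodes): row T holds 1/3 at the FE
      indices of triangle T's vertices, so ``A_map @ phi_FE`` is the vector
      of BE element potentials (the potential-matching map);
    * ``F`` (n_fe_nodes x n_triangles): column T adds
      -sigma_BE * Area_T / 3 to each vertex of T (the flux surface term
      entering the FE load side; moved to the left-hand side by negation
      during assembly).

    ``fe_node_index`` maps parent-mesh node id -> FE unknown index (-1 for
    nodes absent from the FE submesh; any such triangle vertex is an
    orphan and a hard error).
    """
    tri_fe = fe_node_index[surface.triangles]
    if np.any(tri_fe < 0):
        bad = int(np.argmax((tri_fe < 0).any(axis=1)))
        raise ValueError(f"interface triangle {bad} has no matching FE nodes")
    t = surface.n_triangles
    rows = np.repeat(np.arange(t), 3)
    A_map = sp.coo_array(
        (np.full(3 * t, 1.0 / 3.0), (rows, tri_fe.ravel())),
        shape=(t, n_fe_nodes)).tocsr()
    areas = surface.areas()
    F = sp.coo_array(
        (np.repeat(-sigma_be * areas / 3.0, 3), (tri_fe.ravel(), rows)),
        shape=(n_fe_nodes, t)).tocsr()
    return A_map, F


@dataclass
class HybridSystem:
    """Assembled coupled system over unknowns (phi_FE, p-bar_BE).

    Block layout (n_fe + n_be unknowns, before deflation):
        [ K_FE      C  ] [phi_FE]   [ 0   ]
        [ G        D1  ] [p_bar ] = [ s   ]
    where C carries the interface flux term, G the BE collocation rows
    after substituting the 3-node averages for the interface potentials,
    and s the dipole source terms.  The interface potentials themselves are
    recovered from ``A_map @ phi_FE``.
    """

    K: sp.csr_array            # FE block (n_fe x n_fe)
    C: sp.csr_array            # flux coupling (n_fe x n_be)
    G: np.ndarray              # BE rows on FE unknowns (n_be x n_fe), dense
    D1: np.ndarray             # BE rows on p-bar unknowns (n_be x n_be)
    s: np.ndarray              # BE right-hand side
    interface: InterfaceSurface
    A_map: sp.csr_array
    fe_nodes_parent: np.ndarray       # FE unknown -> parent mesh node id
    scalp_nodes_fe: np.ndarray        # FE unknown indices on the scalp
    mesh: LabeledTetMesh
    sigma_be: float
    meta: dict = field(default_factory=dict)

    @property
    def n_fe(self) -> int:
        return self.K.shape[0]

    @property
    def n_be(self) -> int:
        return self.D1.shape[0]


class HybridOperator:
    """Hybrid BE-FE solver on a fixed labeled mesh.

    Geometry blocks (BE influence matrices, FE stiffness structure,
    interface maps) are cached; per-realization assembly only rescales
    conductivities and rebuilds the dipole source term.
    """

    def __init__(self, mesh: LabeledTetMesh, spec: SphereModelSpec | None = None,
                 assignment: RegionAssignment | None = None,
                 anisotropic_skull: bool = False):
        labels = [int(l) for l in mesh.labels_present]
        self.mesh = mesh
        self.spec = spec
        self.assignment = assignment or RegionAssignment.brain_be(labels)
        aniso_regions = ()
        if anisotropic_skull:
            if spec is None or spec.skull_layer is None:
                raise ValueError("anisotropic skull requires a model spec")
            aniso_regions = (spec.skull_layer,)
        self.anisotropic_skull = anisotropic_skull
        self.assignment.validate(labels, dipole_region=min(labels),
                                 anisotropic_regions=aniso_regions)
        be_regions = [l for l in labels if self.assignment.method[l] == "BE"]
        if be_regions != [min(labels)]:
            raise ValueError("exactly the innermost region must be BE here")
        self.be_region = be_regions[0]
        self.fe_regions = [l for l in labels if self.assignment.method[l] == "FE"]

        # interface between the BE region and the FE domain
        surfaces = extract_interfaces(mesh)
        self.interface = next(
            s for s in surfaces if s.inner_region == self.be_region)
        # FE submesh over the remaining regions
        self.fe_mesh, self.fe_nodes_parent = mesh.restricted(self.fe_regions)
        self._parent_to_fe = -np.ones(mesh.n_nodes, np.int64)
        self._parent_to_fe[self.fe_nodes_parent] = np.arange(
            self.fe_nodes_parent.size)
        self.scalp_nodes_fe = _outer_boundary_nodes_of_full_domain(
            self.fe_mesh, self.fe_nodes_parent, mesh)

        # per-region unit stiffness cache (on FE submesh numbering)
        eye = np.eye(3)
        self._unit_K = {}
        self._fixed_K = None
        skull = spec.skull_layer if (spec is not None and anisotropic_skull) else None
        for lab in self.fe_regions:
            mask = self.fe_mesh.region_label == lab
            sub = LabeledTetMesh(nodes=self.fe_mesh.nodes,
                                 tets=self.fe_mesh.tets[mask],
                                 region_label=self.fe_mesh.region_label[mask])
            if lab == skull:
                assign = ConductivityAssignment(
                    radial_anisotropic={lab: spec.skull_anisotropy},
                    isotropic={})
                self._fixed_K = assemble_stiffness(
                    sub, assign.element_tensors(sub))
            else:
                self._unit_K[lab] = assemble_stiffness(
                    sub, eye[None].repeat(mask.sum(), 0))
        self.skull_label = skull

        # BE influence blocks on the interface (collocation at centroids)
        cents = self.interface.centroids()
        self._D1, self._D2 = d1_d2_matrices(self.interface, cents)
        np.fill_diagonal(self._D2, 0.0)

        # interface maps (conductivity-independent parts)
        tri_fe = self._parent_to_fe[self.interface.triangles]
        if np.any(tri_fe < 0):
            raise ValueError("interface triangle without matching FE face")
        t = self.interface.n_triangles
        rows = np.repeat(np.arange(t), 3)
        self.A_map = sp.coo_array(
            (np.full(3 * t, 1.0 / 3.0), (rows, tri_fe.ravel())),
            shape=(t, self.fe_nodes_parent.size)).tocsr()
        self._areas = self.interface.areas()
        self._tri_fe = tri_fe

    def fe_stiffness(self, conductivities) -> sp.csr_array:
        sig = np.asarray(conductivities, float)
        K = self._fixed_K.copy() if self._fixed_K is not None else None
        for lab in self.fe_regions:
            if lab == self.skull_label:
                continue
            term = sig[lab - 1] * self._unit_K[lab]
            K = term if K is None else K + term
        return K

    def assemble(self, conductivities, dipole: Dipole,
                 source_form: str = "element_mean") -> HybridSystem:
        sig = np.asarray(conductivities, float)
        sigma_be = float(sig[self.be_region - 1])
        r_dip = np.linalg.norm(dipole.position)
        if r_dip >= np.linalg.norm(self.interface.centroids(), axis=1).min():
            raise ValueError("dipole must lie strictly inside the BE region")

        K = self.fe_stiffness(sig)
        n_fe = K.shape[0]
        t = self.interface.n_triangles

        # flux coupling: FE weak form surface term moved to the LHS gives
        # + sigma_BE * Area_T/3 at each vertex of triangle T
        C = sp.coo_array(
            (np.repeat(sigma_be * self._areas / 3.0, 3),
             (self._tri_fe.ravel(), np.repeat(np.arange(t), 3))),
            shape=(n_fe, t)).tocsr()

        # BE collocation rows: (1/2) phi_m - sum_k phi_k D2 + sum_k p_k D1 = s
        # with phi substituted by the 3-node FE averages of the
        # potential-matching map.
        half_minus_D2 = 0.5 * np.eye(t) - self._D2
        G = half_minus_D2 @ self.A_map.toarray()

        cents = self.interface.centroids()
        if source_form == "element_mean":
            s = -dipole_source_element_means(self.interface, dipole, sigma_be)
        else:
            s = -dipole_source_term(dipole, sigma_be, cents, form=source_form)

        return HybridSystem(
            K=K, C=C, G=G, D1=self._D1.copy(), s=s,
            interface=self.interface, A_map=self.A_map,
            fe_nodes_parent=self.fe_nodes_parent,
            scalp_nodes_fe=self.scalp_nodes_fe,
            mesh=self.mesh, sigma_be=sigma_be,
            meta={"conductivities": sig.tolist(),
                  "anisotropic_skull": self.anisotropic_skull,
                  "source_form": source_form,
                  "dipole_position": dipole.position.tolist(),
                  "dipole_moment": dipole.moment.tolist()},
        )

    def solve(self, conductivities, dipole: Dipole, **kw) -> ForwardSolution:
        return solve_hybrid(self.assemble(conductivities, dipole, **kw))

    def factorize(self, conductivities, source_form: str = "element_mean"
                  ) -> "HybridFactorization":
        """Factorize the coupled system once per conductivity draw."""
        return HybridFactorization(self, conductivities, source_form)


class HybridFactorization:
    """Schur-complement factorization of one conductivity draw.

    All blocks of the coupled system are dipole-independent; only the BE
    source vector changes per dipole, so sweeps over dipoles reuse the FE
    sparse factorization and the dense Schur LU.
    """

    def __init__(self, operator: HybridOperator, conductivities,
                 source_form: str = "element_mean"):
        self.op = operator
        self.sig = np.asarray(conductivities, float)
        self.source_form = source_form
        r1 = np.linalg.norm(operator.interface.centroids(), axis=1).min()
        probe = Dipole(position=np.array([0.0, 0.0, 0.25 * r1]),
                       direction=np.array([0.0, 0.0, 1.0]))
        system = operator.assemble(self.sig, probe, source_form)
        self.system = system
        n_fe, n_be = system.n_fe, system.n_be
        ones = np.ones((n_fe, 1)) / n_fe
        K_aug = sp.bmat([[system.K, sp.csr_array(ones)],
                         [sp.csr_array(ones.T), None]], format="csc")
        lu = spla.splu(K_aug)
        C_aug = np.vstack([system.C.toarray(), np.zeros((1, n_be))])
        self._KinvC = lu.solve(C_aug)
        G_aug = np.hstack([system.G, np.zeros((n_be, 1))])
        S = system.D1 - G_aug @ self._KinvC
        self._S_lu = scipy.linalg.lu_factor(S)
        self._n_fe = n_fe

    def solve(self, dipole: Dipole) -> ForwardSolution:
        op, system = self.op, self.system
        sigma_be = system.sigma_be
        if self.source_form == "element_mean":
            s = -dipole_source_element_means(op.interface, dipole, sigma_be)
        else:
            s = -dipole_source_term(dipole, sigma_be,
                                    op.interface.centroids(),
                                    form=self.source_form)
        p = scipy.linalg.lu_solve(self._S_lu, s)
        x = -self._KinvC @ p
        phi_fe = x[:self._n_fe]
        scalp = system.scalp_nodes_fe
        pots = phi_fe[scalp] - phi_fe[scalp].mean()
        return ForwardSolution(
            points=system.mesh.nodes[system.fe_nodes_parent[scalp]],
            potentials=pots,
            referencing="average",
            meta={**system.meta, "method": "hybrid",
                  "p_bar": p, "phi_interface": system.A_map @ phi_fe,
                  "dipole_position": dipole.position.tolist(),
                  "dipole_moment": dipole.moment.tolist()},
        )


def assemble_hybrid(
    mesh: LabeledTetMesh,
    conductivities,
    dipole: Dipole,
    spec: SphereModelSpec | None = None,
    assignment: RegionAssignment | None = None,
    anisotropic_skull: bool = False,
) -> HybridSystem:
    """One-shot assembly (see :class:`HybridOperator` for the cached form)."""
    op = HybridOperator(mesh, spec=spec, assignment=assignment,
                        anisotropic_skull=anisotropic_skull)
    return op.assemble(conductivities, dipole)


def solve_hybrid(system: HybridSystem, tol: float = 1e-8) -> ForwardSolution:
    """Solve the coupled block system in one step.

    The FE block (with a mean-zero Lagrange constraint deflating the global
    constant) is factorized sparsely and eliminated from the BE rows; the
    dense Schur complement in the flux unknowns is solved directly, then the
    FE potentials are recovered.  Returns average-referenced scalp nodal
    potentials.
    """
    n_fe, n_be = system.n_fe, system.n_be
    ones = np.ones((n_fe, 1)) / n_fe
    K_aug = sp.bmat([[system.K, sp.csr_array(ones)],
                     [sp.csr_array(ones.T), None]], format="csc")
    lu = spla.splu(K_aug)

    # eliminate (phi_FE, mu) from the BE rows:  S p = s - G K^-1 * 0
    C_aug = np.vstack([system.C.toarray(), np.zeros((1, n_be))])
    KinvC = lu.solve(C_aug)
    G_aug = np.hstack([system.G, np.zeros((n_be, 1))])
    S = system.D1 - G_aug @ KinvC
    p = scipy.linalg.solve(S, system.s)
    x = -KinvC @ p
    phi_fe = x[:n_fe]

    resid = np.linalg.norm(system.G @ phi_fe + system.D1 @ p - system.s)
    scale = np.linalg.norm(system.s)
    if scale > 0 and resid / scale > tol:
        raise RuntimeError(
            f"hybrid solve residual {resid / scale:.2e} exceeds {tol:.0e} "
            f"(FE block {n_fe}, BE block {n_be})")

    scalp = system.scalp_nodes_fe
    pots = phi_fe[scalp] - phi_fe[scalp].mean()
    phi_interface = system.A_map @ phi_fe
    return ForwardSolution(
        points=system.mesh.nodes[system.fe_nodes_parent[scalp]],
        potentials=pots,
        referencing="average",
        meta={**system.meta, "method": "hybrid",
              "p_bar": p, "phi_interface": phi_interface,
              "phi_fe": phi_fe,
              "n_fe": n_fe, "n_be": n_be},
    )


def _outer_boundary_nodes_of_full_domain(
    fe_mesh: LabeledTetMesh, fe_nodes_parent: np.ndarray,
    full_mesh: LabeledTetMesh,
) -> np.ndarray:
    """FE-submesh indices of nodes on the scalp (outer boundary of the FULL
    head, not the inner boundary the FE submesh also has)."""
    outer_parent = _outer_boundary_nodes(full_mesh)
    parent_to_fe = -np.ones(full_mesh.n_nodes, np.int64)
    parent_to_fe[fe_nodes_parent] = np.arange(fe_nodes_parent.size)
    idx = parent_to_fe[outer_parent]
    return np.unique(idx[idx >= 0])
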