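import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from eegfwd.fem import (ConductivityAssignment, FEMOperator,
                        assemble_and_solve_fem, assemble_stiffness,
                        element_stiffness, pi_load, shape_gradients)
from eegfwd.geometry import Dipole, TetLocator, place_dipole

from conftest import closed_form_homogeneous_radial, rdm_of


def quadrature_stiffness(nodes4, tensor, n=6):
    """Independent element-stiffness oracle: numerically differentiate the
    P1 shape functions (finite differences) and midpoint-integrate."""
    nodes4 = np.asarray(nodes4, float)
    # shape function j solves N_j(node_i) = delta_ij with N = a+bx+cy+dz
    V = np.abs(np.linalg.det((nodes4[1:] - nodes4[0]).T)) / 6.0
    A = np.column_stack([np.ones(4), nodes4])
    coef = np.linalg.inv(A)               # column j: coefficients of N_j
    grads = coef[1:, :].T                 # (4, 3) exact constant gradients
    return V * grads @ tensor @ grads.T


UNIT_TET = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)


class TestElementStiffness:
    def test_unit_tet_matches_quadrature_oracle(self):
        K = element_stiffness(UNIT_TET, np.eye(3))
        np.testing.assert_allclose(K, quadrature_stiffness(UNIT_TET, np.eye(3)),
                                   atol=1e-12)

    def test_random_tets_match_oracle_with_anisotropy(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            nodes = rng.normal(size=(4, 3))
            if np.linalg.det((nodes[1:] - nodes[0]).T) < 0:
                nodes[[2, 3]] = nodes[[3, 2]]
            Q = rng.normal(size=(3, 3))
            tensor = Q @ Q.T + 0.1 * np.eye(3)
            np.testing.assert_allclose(
                element_stiffness(nodes, tensor),
                quadrature_stiffness(nodes, tensor), atol=1e-10)

    def test_constant_field_carries_no_current(self):
        rng = np.random.default_rng(0)
        nodes = rng.normal(size=(4, 3))
        if np.linalg.det((nodes[1:] - nodes[0]).T) < 0:
            nodes[[2, 3]] = nodes[[3, 2]]
        K = element_stiffness(nodes, np.diag([0.3, 0.5, 0.1]))
        np.testing.assert_allclose(K @ np.ones(4), 0, atol=1e-12)

    def test_frame_invariance(self):
        rng = np.random.default_rng(1)
        nodes = rng.normal(size=(4, 3))
        if np.linalg.det((nodes[1:] - nodes[0]).T) < 0:
            nodes[[2, 3]] = nodes[[3, 2]]
        tensor = np.diag([0.2, 0.4, 0.7])
        R = Rotation.from_rotvec([0.3, -1.1, 0.4]).as_matrix()
        K1 = element_stiffness(nodes, tensor)
        K2 = element_stiffness(nodes @ R.T, R @ tensor @ R.T)
        np.testing.assert_allclose(K1, K2, atol=1e-12)

    def test_inverted_tet_rejected(self):
        bad = UNIT_TET[[0, 2, 1, 3]]
        with pytest.raises(ValueError):
            element_stiffness(bad, np.eye(3))

    def test_vectorized_assembly_matches_per_element(self, cube_mesh):
        tensors = np.repeat(np.eye(3)[None], cube_mesh.n_tets, axis=0)
        K = assemble_stiffness(cube_mesh, tensors).toarray()
        K_ref = np.zeros_like(K)
        for tet in cube_mesh.tets:
            Ke = element_stiffness(cube_mesh.nodes[tet], np.eye(3))
            K_ref[np.ix_(tet, tet)] += Ke
        np.testing.assert_allclose(K, K_ref, atol=1e-12)


class TestConductivityAssignment:
    def test_radial_rule_with_equal_sigmas_is_isotropic(self, mesh3_coarse):
        iso = ConductivityAssignment(isotropic={1: 0.3, 2: 0.02, 3: 0.5})
        aniso = ConductivityAssignment(
            isotropic={1: 0.3, 3: 0.5},
            radial_anisotropic={2: (0.02, 0.02)})
        np.testing.assert_allclose(iso.element_tensors(mesh3_coarse),
                                   aniso.element_tensors(mesh3_coarse),
                                   atol=1e-18)

    def test_tensors_spd_for_anisotropic_skull(self, spec3, mesh3_coarse):
        assign = ConductivityAssignment.from_spec(
            spec3, [0.4, 0.02, 0.5], anisotropic_skull=True)
        T = assign.element_tensors(mesh3_coarse)
        eig = np.linalg.eigvalsh(T)
        assert eig.min() > 0
        skull = mesh3_coarse.region_label == 2
        np.testing.assert_allclose(np.sort(eig[skull], axis=1)[:, 0], 0.0093)

    def test_missing_region_rule_rejected(self, mesh3_coarse):
        with pytest.raises(ValueError, match="no conductivity rule"):
            ConductivityAssignment(isotropic={1: 0.3}).element_tensors(
                mesh3_coarse)


class TestPILoad:
    def test_load_sums_to_zero(self, mesh3_coarse):
        d = Dipole(position=[0, 0, 0.031], direction=[0.6, 0, 0.8])
        B = pi_load(d, mesh3_coarse)
        assert abs(B.sum()) < 1e-15 * np.abs(B).max()
        assert np.count_nonzero(B) <= 4

    def test_flipping_moment_negates_load(self, mesh3_coarse):
        loc = TetLocator(mesh3_coarse)
        up = pi_load(Dipole(position=[0, 0, 0.02], direction=[0, 0, 1]),
                     mesh3_coarse, loc)
        down = pi_load(Dipole(position=[0, 0, 0.02], direction=[0, 0, -1]),
                       mesh3_coarse, loc)
        np.testing.assert_allclose(up, -down)

    def test_monopole_pair_converges_to_point_form(self, mesh3_coarse):
        loc = TetLocator(mesh3_coarse)
        d = Dipole(position=[0.001, 0.002, 0.0213], direction=[0, 0, 1])
        point = pi_load(d, mesh3_coarse, loc)
        mono = pi_load(d, mesh3_coarse, loc, form="monopole", separation=1e-7)
        np.testing.assert_allclose(mono, point, atol=1e-4 * np.abs(point).max())

    def test_dipole_outside_mesh_rejected(self, mesh3_coarse):
        with pytest.raises(ValueError):
            pi_load(Dipole(position=[0, 0, 0.5], direction=[0, 0, 1]),
                    mesh3_coarse)


class TestSolve:
    def test_homogeneous_sphere_matches_closed_form(self, mesh1_coarse):
        d = Dipole(position=[0, 0, 0.048], direction=[0, 0, 1])
        sol = assemble_and_solve_fem(mesh1_coarse, [0.33], d)
        want = closed_form_homogeneous_radial(0.092, 0.33, 0.048, 1.0,
                                              sol.points)
        assert rdm_of(want, sol.potentials) < 0.1

    def test_equal_conductivity_layers_match_homogeneous(self, spec3,
                                                         mesh3_coarse):
        d = place_dipole(spec3, 50, "radial")
        sol = assemble_and_solve_fem(mesh3_coarse, [0.33, 0.33, 0.33], d)
        want = closed_form_homogeneous_radial(0.092, 0.33, d.position[2], 1.0,
                                              sol.points)
        assert rdm_of(want, sol.potentials) < 0.1

    def test_conductivity_scaling_divides_potentials(self, spec3,
                                                     mesh3_coarse):
        d = place_dipole(spec3, 60, "radial")
        op = FEMOperator(mesh3_coarse, spec3)
        one = op.solve([0.4, 0.02, 0.5], d)
        half = op.solve([0.8, 0.04, 1.0], d)
        np.testing.assert_allclose(2 * half.potentials, one.potentials,
                                   rtol=1e-8)

    def test_residual_contract(self, spec3, mesh3_coarse):
        d = place_dipole(spec3, 70, "tangential")
        op = FEMOperator(mesh3_coarse, spec3)
        sol = op.solve([0.4, 0.02, 0.5], d)
        K = op.stiffness([0.4, 0.02, 0.5])
        B = pi_load(d, mesh3_coarse, op.locator)
        phi = sol.meta["nodal_potentials"]
        assert np.linalg.norm(K @ phi - B) <= 1e-10 * np.linalg.norm(B)

    def test_anisotropic_with_equal_sigmas_matches_isotropic(
            self, spec3, mesh3_coarse):
        """Radially anisotropic skull rule with sigma_r = sigma_t must
        reproduce the isotropic solve."""
        import dataclasses
        spec_eq = dataclasses.replace(spec3, skull_anisotropy=(0.02, 0.02))
        d = place_dipole(spec3, 60, "radial")
        iso = FEMOperator(mesh3_coarse, spec3).solve([0.4, 0.02, 0.5], d)
        aniso = FEMOperator(mesh3_coarse, spec_eq,
                            anisotropic_skull=True).solve([0.4, 0.99, 0.5], d)
        np.testing.assert_allclose(aniso.potentials, iso.potentials,
                                   rtol=1e-9)

    def test_factorized_matches_direct(self, spec3, mesh3_coarse):
        d = place_dipole(spec3, 80, "radial")
        op = FEMOperator(mesh3_coarse, spec3)
        direct = op.solve([0.4, 0.02, 0.5], d)
        fact = op.factorize([0.4, 0.02, 0.5])
        np.testing.assert_allclose(fact.solve(d).potentials,
                                   direct.potentials, rtol=1e-9)

    def test_h_convergence_homogeneous(self, spec1, mesh1_coarse):
        from eegfwd.geometry import refine_mesh
        d = Dipole(position=[0, 0, 0.048], direction=[0, 0, 1])
        fine = refine_mesh(mesh1_coarse, snap_spheres=spec1.radii_m)
        e = []
        for m in (mesh1_coarse, fine):
            sol = assemble_and_solve_fem(m, [0.33], d)
            want = closed_form_homogeneous_radial(0.092, 0.33, 0.048, 1.0,
                                                  sol.points)
            e.append(rdm_of(want, sol.potentials))
        assert e[1] < e[0]
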