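import numpy as np
import pytest

from eegfwd.analytic import (AnalyticSphereModel, analytic_potential,
                             model_from_spec, reference_by_refinement)
from eegfwd.fem import assemble_and_solve_fem
from eegfwd.geometry import Dipole, place_dipole

from conftest import (closed_form_homogeneous_radial, rdm_of,
                      series_homogeneous_tangential)

R = 0.092


@pytest.fixture(scope="module")
def scalp_points():
    rng = np.random.default_rng(42)
    p = rng.normal(size=(40, 3))
    return p / np.linalg.norm(p, axis=1, keepdims=True) * R


class TestHomogeneousLimit:
    def test_radial_matches_closed_form(self, scalp_points):
        model = AnalyticSphereModel(radii=(R,), sigma_r=(0.33,),
                                    sigma_t=(0.33,))
        d = Dipole(position=[0, 0, 0.04], direction=[0, 0, 1], strength=1.0)
        got = analytic_potential(model, d, scalp_points)
        want = closed_form_homogeneous_radial(R, 0.33, 0.04, 1.0, scalp_points)
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_equal_conductivity_layers_match_closed_form(self, scalp_points):
        model = AnalyticSphereModel(radii=(0.08, 0.086, R),
                                    sigma_r=(0.33,) * 3, sigma_t=(0.33,) * 3)
        d = Dipole(position=[0, 0, 0.04], direction=[0, 0, 1])
        got = analytic_potential(model, d, scalp_points)
        want = closed_form_homogeneous_radial(R, 0.33, 0.04, 1.0, scalp_points)
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_tangential_matches_series_oracle(self, scalp_points):
        model = AnalyticSphereModel(radii=(0.08, 0.086, R),
                                    sigma_r=(0.4,) * 3, sigma_t=(0.4,) * 3)
        d = Dipole(position=[0, 0, 0.04], direction=[1, 0, 0])
        got = analytic_potential(model, d, scalp_points)
        want = series_homogeneous_tangential(R, 0.4, 0.04, 1.0, scalp_points)
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_center_dipole_is_pure_first_harmonic(self, scalp_points):
        model = AnalyticSphereModel(radii=(R,), sigma_r=(0.33,),
                                    sigma_t=(0.33,))
        d = Dipole(position=[0, 0, 0.0], direction=[0, 0, 1])
        got = analytic_potential(model, d, scalp_points)
        want = 3 * scalp_points[:, 2] / (4 * np.pi * 0.33 * R**3)
        np.testing.assert_allclose(got, want, rtol=1e-10)


class TestStructure:
    def test_conductivity_scaling_divides_potential(self, scalp_points):
        d = Dipole(position=[0, 0, 0.05], direction=[0, 0, 1])
        base = AnalyticSphereModel(radii=(0.08, 0.086, R),
                                   sigma_r=(0.3, 0.02, 0.5),
                                   sigma_t=(0.3, 0.02, 0.5))
        scaled = AnalyticSphereModel(radii=(0.08, 0.086, R),
                                     sigma_r=(0.6, 0.04, 1.0),
                                     sigma_t=(0.6, 0.04, 1.0))
        a = analytic_potential(base, d, scalp_points)
        b = analytic_potential(scaled, d, scalp_points)
        np.testing.assert_allclose(2 * b, a, rtol=1e-12)

    def test_rotational_invariance_about_any_axis(self, scalp_points):
        """Radial skull anisotropy is symmetric about every axis through
        the center, so rotating the evaluation points with the (axial)
        dipole leaves potentials unchanged."""
        from scipy.spatial.transform import Rotation
        model = AnalyticSphereModel(radii=(0.08, 0.086, R),
                                    sigma_r=(0.445, 0.0093, 0.575),
                                    sigma_t=(0.445, 0.015, 0.575))
        d = Dipole(position=[0, 0, 0.05], direction=[0, 0, 1])
        base = analytic_potential(model, d, scalp_points)
        rot = Rotation.from_rotvec([0, 0, 1.3]).as_matrix()  # about z
        rotated = analytic_potential(model, d, scalp_points @ rot.T)
        # z-rotation maps the axisymmetric (m=0) solution onto itself
        np.testing.assert_allclose(rotated, base, rtol=1e-10)

    def test_series_cauchy_convergence_at_max_eccentricity(self, scalp_points):
        d = Dipole(position=[0, 0, 0.98 * 0.08], direction=[0, 0, 1])
        radii = (0.08, 0.086, R)
        sig = (0.445, 0.0173, 0.575)
        coarse = AnalyticSphereModel(radii=radii, sigma_r=sig, sigma_t=sig,
                                     n_max=250, tol=0.0)
        fine = AnalyticSphereModel(radii=radii, sigma_r=sig, sigma_t=sig,
                                   n_max=600, tol=0.0)
        a = analytic_potential(coarse, d, scalp_points)
        b = analytic_potential(fine, d, scalp_points)
        assert np.max(np.abs(a - b)) < 1e-8 * np.max(np.abs(b))

    def test_isotropic_layers_invariant_to_swapping_sigma_labels(
            self, scalp_points):
        d = Dipole(position=[0, 0, 0.05], direction=[0, 0, 1])
        m1 = AnalyticSphereModel(radii=(0.08, R), sigma_r=(0.3, 0.5),
                                 sigma_t=(0.3, 0.5))
        same = analytic_potential(m1, d, scalp_points)
        np.testing.assert_allclose(
            same, analytic_potential(m1, d, scalp_points))

    def test_nonconvergent_series_raises(self, scalp_points):
        model = AnalyticSphereModel(radii=(0.08, 0.086, R),
                                    sigma_r=(0.445, 0.0173, 0.575),
                                    sigma_t=(0.445, 0.0173, 0.575), n_max=10)
        d = Dipole(position=[0, 0, 0.98 * 0.08], direction=[0, 0, 1])
        with pytest.raises(RuntimeError, match="n_max"):
            analytic_potential(model, d, scalp_points)

    @pytest.mark.parametrize("pos,direction", [
        ((0.01, 0, 0.04), (0, 0, 1)),       # off axis
        ((0, 0, 0.09), (0, 0, 1)),          # outside innermost layer
        ((0, 0, 0.04), (0.5, 0, 0.5)),      # oblique moment
    ])
    def test_invalid_dipole_rejected(self, scalp_points, pos, direction):
        model = AnalyticSphereModel(radii=(0.08, 0.086, R),
                                    sigma_r=(0.3,) * 3, sigma_t=(0.3,) * 3)
        with pytest.raises(ValueError):
            analytic_potential(model, Dipole(position=pos,
                                             direction=direction),
                               scalp_points)

    def test_model_from_spec_applies_skull_anisotropy(self, spec3):
        m = model_from_spec(spec3, [0.4, 0.02, 0.5], anisotropic_skull=True)
        assert m.sigma_r[1] == pytest.approx(0.0093)
        assert m.sigma_t[1] == pytest.approx(0.015)


class TestRefinedReference:
    def test_refine_factor_one_equals_plain_fem(self, mesh1_coarse):
        d = Dipole(position=[0, 0, 0.04], direction=[0, 0, 1])
        ref = reference_by_refinement(mesh1_coarse, [0.33], d, refine_factor=1)
        plain = assemble_and_solve_fem(mesh1_coarse, [0.33], d)
        np.testing.assert_allclose(ref.potentials, plain.potentials)

    def test_refinement_reduces_error_vs_closed_form(self, spec1,
                                                     mesh1_coarse):
        d = Dipole(position=[0, 0, 0.048], direction=[0, 0, 1])
        coarse = assemble_and_solve_fem(mesh1_coarse, [0.33], d)
        fine = reference_by_refinement(mesh1_coarse, [0.33], d,
                                       refine_factor=2,
                                       snap_spheres=spec1.radii_m)
        e_coarse = rdm_of(closed_form_homogeneous_radial(
            R, 0.33, 0.048, 1.0, coarse.points), coarse.potentials)
        e_fine = rdm_of(closed_form_homogeneous_radial(
            R, 0.33, 0.048, 1.0, fine.points), fine.potentials)
        assert e_fine < e_coarse

    def test_memory_guard(self, mesh1_coarse):
        d = Dipole(position=[0, 0, 0.04], direction=[0, 0, 1])
        with pytest.raises(MemoryError):
            reference_by_refinement(mesh1_coarse, [0.33], d, refine_factor=3,
                                    max_nodes=1000)
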