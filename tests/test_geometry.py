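import numpy as np
import pytest

from eegfwd.geometry import (Dipole, MeshDensity, SphereModelSpec, TetLocator,
                             build_sphere_mesh, extract_interfaces,
                             four_layer_model, place_dipole, refine_mesh,
                             sphere_triangulation, three_layer_model)


class TestSphereMesh:
    def test_tet_volumes_positive_and_shell_volumes(self, spec3, mesh3_coarse):
        vols = mesh3_coarse.tet_volumes()
        assert np.all(vols > 0)
        r = np.concatenate([[0.0], spec3.radii_m])
        for lab in (1, 2, 3):
            v = vols[mesh3_coarse.region_label == lab].sum()
            exact = 4 / 3 * np.pi * (r[lab]**3 - r[lab - 1]**3)
            # polyhedral volume deficit at this coarse angular resolution
            assert abs(v / exact - 1) < 0.03

    def test_centroid_radii_lie_in_region_shells(self, spec3, mesh3_coarse):
        c = np.linalg.norm(mesh3_coarse.tet_centroids(), axis=1)
        bounds = np.concatenate([[0.0], spec3.radii_m])
        for lab in (1, 2, 3):
            cc = c[mesh3_coarse.region_label == lab]
            assert cc.min() > bounds[lab - 1] - 1e-12
            assert cc.max() < bounds[lab] + 1e-12

    def test_relabeling_by_centroid_radius_reproduces_labels(
            self, spec3, mesh3_coarse):
        c = np.linalg.norm(mesh3_coarse.tet_centroids(), axis=1)
        relabel = 1 + np.searchsorted(spec3.radii_m[:-1], c)
        assert np.array_equal(relabel, mesh3_coarse.region_label)

    def test_element_counts_scale_with_density(self, spec3):
        counts = []
        for f in (0.5, 1.0, 2.0):
            dens = MeshDensity(n_surface=int(200 * f), inner_layers=3,
                               outer_layers=(1, 1))
            counts.append(build_sphere_mesh(spec3, density=dens, seed=0).n_tets)
        assert counts[0] < counts[1] < counts[2]

    def test_deterministic_under_fixed_seed(self, spec3):
        dens = MeshDensity(n_surface=150, inner_layers=2, outer_layers=(1, 1))
        a = build_sphere_mesh(spec3, density=dens, seed=7)
        b = build_sphere_mesh(spec3, density=dens, seed=7)
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.tets, b.tets)

    def test_reference_scale_counts_three_layer(self):
        spec = three_layer_model()
        mesh = build_sphere_mesh(spec, seed=1)
        assert abs(mesh.n_nodes / 6808 - 1) < 0.25
        assert abs(mesh.n_tets / 34428 - 1) < 0.25
        # shell volumes within 2% at this resolution
        vols = mesh.tet_volumes()
        r = np.concatenate([[0.0], spec.radii_m])
        for lab in (1, 2, 3):
            v = vols[mesh.region_label == lab].sum()
            exact = 4 / 3 * np.pi * (r[lab]**3 - r[lab - 1]**3)
            assert abs(v / exact - 1) < 0.02

    def test_reference_scale_counts_four_layer(self):
        mesh = build_sphere_mesh(four_layer_model(), seed=1)
        assert abs(mesh.n_nodes / 14350 - 1) < 0.25
        assert abs(mesh.n_tets / 81942 - 1) < 0.25

    def test_unit_ball_volume(self):
        spec = SphereModelSpec(radii_cm=(100.0,),
                               conductivity_intervals=((1.0, 1.0),),
                               layer_names=("ball",))
        mesh = build_sphere_mesh(
            spec, density=MeshDensity(n_surface=800, inner_layers=8), seed=0)
        assert abs(mesh.tet_volumes().sum() / (4 / 3 * np.pi) - 1) < 0.02

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SphereModelSpec(radii_cm=(9.2, 8.0),
                            conductivity_intervals=((1, 1), (1, 1)),
                            layer_names=("a", "b"))
        with pytest.raises(ValueError):
            SphereModelSpec(radii_cm=(8.0,),
                            conductivity_intervals=((0.0, 1.0),),
                            layer_names=("a",))


class TestInterfaces:
    def test_three_closed_surfaces_with_sphere_areas(
            self, spec3, surfaces3_coarse):
        assert len(surfaces3_coarse) == 3
        for s in surfaces3_coarse:
            r = spec3.radii_m[s.inner_region - 1]
            assert abs(s.total_area() / (4 * np.pi * r**2) - 1) < 0.02

    def test_triangle_counts_match_angular_mesh(self, surfaces3_coarse):
        t0 = surfaces3_coarse[0].n_triangles
        assert all(s.n_triangles == t0 for s in surfaces3_coarse)

    def test_outward_orientation(self, surfaces3_coarse):
        for s in surfaces3_coarse:
            # normals point away from the center for nested spheres
            dots = np.einsum("ij,ij->i", s.normals(), s.centroids())
            assert np.all(dots > 0)

    def test_solid_angle_closure_at_random_interior_points(
            self, surfaces3_coarse):
        rng = np.random.default_rng(0)
        for s in surfaces3_coarse:
            r_in = np.linalg.norm(s.centroids(), axis=1).min()
            for _ in range(10):
                p = rng.normal(size=3)
                p = p / np.linalg.norm(p) * rng.uniform(0, 0.5 * r_in)
                assert abs(s.solid_angle(p) - 4 * np.pi) < 1e-3 * 4 * np.pi

    def test_cube_boundary_extraction(self, cube_mesh):
        surfs = extract_interfaces(cube_mesh)
        assert len(surfs) == 1
        s = surfs[0]
        assert s.n_triangles == 12
        assert abs(s.total_area() - 6.0) < 1e-12
        assert s.outer_region == 0

    def test_nonmanifold_face_rejected(self, cube_mesh):
        import copy
        bad = copy.deepcopy(cube_mesh)
        bad.tets = np.vstack([bad.tets, bad.tets[:1]])
        bad.region_label = np.concatenate([bad.region_label, [1]])
        with pytest.raises(ValueError, match="non-manifold"):
            extract_interfaces(bad)

    def test_interface_triangle_count_near_printed_value(self):
        mesh = build_sphere_mesh(three_layer_model(), seed=1)
        surfs = extract_interfaces(mesh)
        brain = next(s for s in surfs if s.inner_region == 1)
        assert abs(brain.n_triangles / 1894 - 1) < 0.25


class TestDipolePlacement:
    @pytest.mark.parametrize("model,ecc,orient,pos,direction", [
        ("three", 98.0, "radial", (0, 0, 0.0784), (0, 0, 1)),
        ("four", 50.0, "tangential", (0, 0, 0.038), (1, 0, 0)),
        ("three", 0.0, "radial", (0, 0, 0.0), (0, 0, 1)),
    ])
    def test_examples(self, model, ecc, orient, pos, direction):
        spec = three_layer_model() if model == "three" else four_layer_model()
        d = place_dipole(spec, ecc, orient)
        np.testing.assert_allclose(d.position, pos, atol=1e-15)
        np.testing.assert_allclose(d.direction, direction)

    def test_eccentricity_above_limit_rejected(self, spec3):
        with pytest.raises(ValueError):
            place_dipole(spec3, 99.0, "radial")

    def test_monopole_representation(self):
        d = Dipole(position=[0, 0, 0.04], direction=[0, 0, 1], strength=2.0)
        r1, r2, current = d.monopoles(1e-4)
        np.testing.assert_allclose(r2 - r1, [0, 0, 1e-4])
        assert current * 1e-4 == pytest.approx(2.0)


class TestRefineAndLocate:
    def test_refine_octuples_and_preserves_volume(self, mesh3_coarse):
        fine = refine_mesh(mesh3_coarse)
        assert fine.n_tets == 8 * mesh3_coarse.n_tets
        assert fine.tet_volumes().sum() == pytest.approx(
            mesh3_coarse.tet_volumes().sum(), rel=1e-12)
        assert np.array_equal(np.repeat(mesh3_coarse.region_label, 8),
                              fine.region_label)

    def test_snap_keeps_interface_on_sphere(self, spec3, mesh3_coarse):
        fine = refine_mesh(mesh3_coarse, snap_spheres=spec3.radii_m)
        surfs = extract_interfaces(fine)
        for s in surfs:
            r = spec3.radii_m[s.inner_region - 1]
            verts = np.unique(s.triangles)
            radii = np.linalg.norm(fine.nodes[verts], axis=1)
            np.testing.assert_allclose(radii, r, rtol=1e-9)

    def test_locator_finds_containing_tet(self, mesh3_coarse):
        loc = TetLocator(mesh3_coarse)
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.normal(size=3)
            p = p / np.linalg.norm(p) * rng.uniform(0, 0.09)
            t, lam = loc.find(p)
            assert lam.min() > -1e-9
            verts = mesh3_coarse.nodes[mesh3_coarse.tets[t]]
            np.testing.assert_allclose(lam @ verts, p, atol=1e-12)

    def test_locator_rejects_outside_points(self, mesh3_coarse):
        with pytest.raises(ValueError):
            TetLocator(mesh3_coarse).find([0.0, 0.0, 0.2])


def test_polar_cap_concentrates_points():
    pts, tris = sphere_triangulation(500, seed=0, cap_fraction=0.3,
                                     cap_angle_deg=25.0)
    zc = np.cos(np.radians(25.0))
    frac_in_cap = (pts[:, 2] > zc).mean()
    cap_area_frac = (1 - zc) / 2
    assert frac_in_cap > 3 * cap_area_frac
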