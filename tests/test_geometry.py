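"""Phantom construction and meshing tests."""

import numpy as np
import pytest

from thyrorfa import geometry as geo
from thyrorfa.fem import tet_volumes


class TestPhantom:
    def test_default_layer_thicknesses(self, phantom):
        assert phantom.layer_thicknesses == {
            "skin": 1e-3, "fat": 6e-3, "muscle": 30e-3, "thyroid": 20e-3}

    def test_nodule_volume_matches_request(self, phantom):
        assert phantom.nodule_volume == pytest.approx(20e-6, rel=1e-3)
        a, b, c = phantom.nodule_semi_axes
        assert 4 / 3 * np.pi * a * b * c == pytest.approx(20e-6, rel=1e-9)

    def test_default_semi_axes_near_reference_shape(self, phantom):
        np.testing.assert_allclose(
            phantom.nodule_semi_axes, (20e-3, 15.9e-3, 15e-3), rtol=1e-3)

    def test_spherical_nodule_radius(self):
        ph = geo.build_phantom(nodule_shape=(1.0, 1.0, 1.0))
        r = (3 * 20e-6 / (4 * np.pi)) ** (1 / 3)
        assert r == pytest.approx(16.84e-3, rel=1e-3)
        assert ph.nodule_semi_axes[0] == pytest.approx(r, rel=1e-9)

    def test_nodule_center_in_thyroid_slab(self, phantom):
        lo, hi = phantom.layer_bounds["thyroid"]
        assert lo < phantom.nodule_center[1] < hi

    def test_zero_volume_rejected(self):
        with pytest.raises(geo.GeometryError):
            geo.build_phantom(nodule_volume=0.0)

    def test_oversized_nodule_rejected(self):
        with pytest.raises(geo.GeometryError, match="along"):
            geo.build_phantom(nodule_volume=2e-3)  # 2 L cannot fit

    def test_electrode_axis_parallel_to_xy_plane(self, phantom):
        el = geo.ElectrodeSpec.centered_in(phantom, 10e-3)
        assert el.insertion_axis[2] == 0.0
        with pytest.raises(geo.GeometryError):
            geo.ElectrodeSpec(tip_length=10e-3,
                              insertion_axis=(0.0, 0.0, 1.0))

    def test_tip_length_bounds(self):
        with pytest.raises(geo.GeometryError):
            geo.ElectrodeSpec(tip_length=0.0)
        with pytest.raises(geo.GeometryError):
            geo.ElectrodeSpec(tip_length=0.2, shaft_length=0.1)


class TestMesh:
    def test_no_inverted_elements_and_volume_conservation(
            self, tiny_mesh_10mm, phantom):
        mesh, _ = tiny_mesh_10mm
        vols = tet_volumes(mesh.nodes, mesh.tets)
        assert np.all(vols > 0)
        assert vols.sum() == pytest.approx(
            np.prod(phantom.domain_extent), rel=5e-3)

    def test_all_regions_present(self, tiny_mesh_10mm):
        mesh, _ = tiny_mesh_10mm
        assert set(np.unique(mesh.region)) == set(range(len(geo.REGIONS)))

    def test_region_volumes_close_to_analytic(self, phantom):
        el = geo.ElectrodeSpec.centered_in(phantom, 10e-3)
        mesh = geo.mesh_phantom(phantom, el, "coarse")
        ex, ey, ez = phantom.domain_extent
        slab_area = ex * ez
        for name in ("skin", "fat"):
            analytic = slab_area * phantom.layer_thicknesses[name]
            assert geo.region_volume(mesh, name) == pytest.approx(
                analytic, rel=0.05)
        assert geo.region_volume(mesh, "nodule") == pytest.approx(
            20e-6, rel=0.05)
        assert geo.region_volume(mesh, "tip") == pytest.approx(
            el.outer_diameter ** 2 * el.tip_length, rel=0.05)

    def test_refinement_reduces_nodule_volume_error(self, phantom):
        el = geo.ElectrodeSpec.centered_in(phantom, 10e-3)
        errs = []
        for opts in (geo.MeshOptions(4e-3, 24e-3, 1.4),
                     geo.MeshOptions(2e-3, 12e-3, 0.7)):
            mesh = geo.mesh_phantom(phantom, el, opts)
            errs.append(abs(geo.region_volume(mesh, "nodule") - 20e-6))
        assert errs[1] < errs[0]

    def test_meshing_deterministic(self, phantom):
        el = geo.ElectrodeSpec.centered_in(phantom, 10e-3)
        m1 = geo.mesh_phantom(phantom, el, "tiny")
        m2 = geo.mesh_phantom(phantom, el, "tiny")
        np.testing.assert_array_equal(m1.tets, m2.tets)
        np.testing.assert_array_equal(m1.nodes, m2.nodes)
        np.testing.assert_array_equal(m1.region, m2.region)

    def test_electrode_outside_domain_rejected(self, phantom):
        el = geo.ElectrodeSpec(tip_length=10e-3,
                               tip_end_point=(0.1, 47e-3, 0.0))
        with pytest.raises(geo.GeometryError):
            geo.mesh_phantom(phantom, el, "tiny")

    def test_tip_outside_nodule_rejected(self, phantom):
        el = geo.ElectrodeSpec(tip_length=5e-3,
                               tip_end_point=(-40e-3, 47e-3, 0.0))
        with pytest.raises(geo.GeometryError, match="nodule"):
            geo.mesh_phantom(phantom, el, "tiny")

    def test_boundary_labels(self, tiny_mesh_10mm):
        mesh, _ = tiny_mesh_10mm
        skin = mesh.boundary_nodes("skin_surface")
        assert np.allclose(mesh.nodes[skin][:, 1], 0.0)
        assert len(mesh.boundary_nodes("outer_ground")) > 0
        tipn = mesh.boundary_nodes("tip_surface")
        assert len(tipn) > 0
        # tip-surface nodes sit on the electrode channel wall
        assert np.all(np.abs(mesh.nodes[tipn][:, 2]) <= 0.636e-3)

    def test_region_volume_unknown_tag(self, tiny_mesh_10mm):
        mesh, _ = tiny_mesh_10mm
        with pytest.raises(KeyError):
            geo.region_volume(mesh, "bone")

    def test_unit_cube_volume(self):
        xs = np.linspace(0, 1, 3)
        nodes, tets = geo.structured_box_mesh(xs, xs, xs)
        assert tet_volumes(nodes, tets).sum() == pytest.approx(1.0)


class TestShellMesh:
    def test_shell_volume_and_surfaces(self):
        a, b = 1e-3, 5e-3
        nodes, tets, inner, outer = geo.spherical_shell_mesh(
            a, b, n_surf=4, n_rad=6)
        vols = tet_volumes(nodes, tets)
        assert np.all(vols > 0)
        exact = 4 / 3 * np.pi * (b ** 3 - a ** 3)
        assert vols.sum() == pytest.approx(exact, rel=0.08)
        assert np.allclose(np.linalg.norm(nodes[inner], axis=1), a, rtol=1e-6)
        assert np.allclose(np.linalg.norm(nodes[outer], axis=1), b, rtol=1e-6)
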