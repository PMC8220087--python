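"""Finite-element verification: patch test, beam-theory oracle,
equilibrium, linearity, meshing and the fissure stress concentration."""

import numpy as np
import pytest

from conftest import truth_labelmap

from discqmri import fem
from discqmri.fem import DiscSectionGeometry, LoadCase, MaterialProps
from discqmri.segmentation import nucleus_boundaries


def homogeneous(E=1000.0, nu=0.0):
    m = MaterialProps(E, nu)
    return {"nucleus": m, "annulus": m}


@pytest.fixture(scope="module")
def beam_setup():
    """Slender homogeneous rectangle under a pure couple on the free end."""
    geo = DiscSectionGeometry(width=2.0, height=20.0, nucleus_x=(0.9, 1.1))
    mats = homogeneous()
    mesh = fem.build_mesh(geo, 0.2)  # edge = height/100 << height/10
    load = LoadCase(moment=0.001, axial_force=0.0, out_of_plane_width=5.0)
    u = fem.solve_elasticity(mesh, mats, load)
    return geo, mats, mesh, load, u


class TestMeshing:
    def test_square_mesh_sanity(self):
        geo = DiscSectionGeometry(width=10.0, height=10.0, nucleus_x=(4.0, 6.0))
        mesh = fem.build_mesh(geo, 1.0)
        assert mesh.elements.shape[0] >= 200
        p = mesh.nodes[mesh.elements[:, :3]]
        areas = 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                       - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
        assert np.all(areas > 0)
        assert set(np.unique(mesh.region_id)) == {"nucleus", "annulus"}

    def test_refinement_quadruples_element_count(self):
        geo = DiscSectionGeometry(width=10.0, height=10.0, nucleus_x=(4.0, 6.0))
        n1 = fem.build_mesh(geo, 1.0).elements.shape[0]
        n2 = fem.build_mesh(geo, 0.5).elements.shape[0]
        assert 4 * n1 * 0.7 <= n2 <= 4 * n1 * 1.3

    def test_interface_conformity(self):
        """Every nucleus-annulus interface edge is shared by exactly two
        elements of different regions."""
        geo = DiscSectionGeometry(width=10.0, height=6.0, nucleus_x=(4.0, 6.0))
        mesh = fem.build_mesh(geo, 1.0)
        edge_owners: dict[tuple[int, int], list[str]] = {}
        for conn, reg in zip(mesh.elements, mesh.region_id):
            for a, b in ((0, 1), (1, 2), (2, 0)):
                key = tuple(sorted((conn[a], conn[b])))
                edge_owners.setdefault(key, []).append(reg)
        iface = [regs for regs in edge_owners.values()
                 if len(regs) == 2 and regs[0] != regs[1]]
        assert len(iface) > 0
        xa = 4.0
        for key, regs in edge_owners.items():
            if len(regs) == 2 and regs[0] != regs[1]:
                xs = mesh.nodes[list(key), 0]
                assert np.allclose(xs, xs[0])  # interface edges are vertical

    def test_notch_removes_elements(self):
        geo = DiscSectionGeometry(width=10.0, height=10.0, nucleus_x=(4.0, 6.0),
                                  notch=(1.0, 3.0, 7.0))
        full = fem.build_mesh(DiscSectionGeometry(width=10.0, height=10.0,
                                                  nucleus_x=(4.0, 6.0)), 0.5)
        notched = fem.build_mesh(geo, 0.5)
        assert notched.elements.shape[0] < full.elements.shape[0]
        assert notched.node_sets["fissure_faces"].size > 0
        c = notched.element_centroids()
        inside = (c[:, 0] < 1.0) & (c[:, 1] > 3.0) & (c[:, 1] < 7.0)
        assert not inside.any()


class TestSolver:
    def test_zero_load_zero_displacement(self):
        geo = DiscSectionGeometry(width=10.0, height=10.0, nucleus_x=(4.0, 6.0))
        mesh = fem.build_mesh(geo, 1.0)
        u = fem.solve_elasticity(mesh, homogeneous(), LoadCase())
        assert np.max(np.abs(u)) == 0.0

    def test_uniform_compression_patch(self):
        """nu = 0 square under uniform pressure: u_y = -sigma h / E exactly."""
        geo = DiscSectionGeometry(width=10.0, height=10.0, nucleus_x=(4.0, 6.0))
        mats = homogeneous(E=100.0, nu=0.0)
        mesh = fem.build_mesh(geo, 1.0)
        load = LoadCase(moment=0.0, axial_force=1000.0, out_of_plane_width=10.0)
        u = fem.solve_elasticity(mesh, mats, load)
        top = mesh.node_sets["superior_plate"]
        np.testing.assert_allclose(u[top, 1], -1.0, rtol=1e-10)

    def test_global_equilibrium(self, beam_setup):
        geo, mats, mesh, load, u = beam_setup
        assert fem.equilibrium_residual(mesh, mats, load, u) < 1e-6

    def test_beam_tip_rotation(self, beam_setup):
        geo, mats, mesh, load, u = beam_setup
        m_line = 1000.0 * load.moment / load.out_of_plane_width
        I = geo.width**3 / 12.0
        theta_ref = m_line * geo.height / (mats["annulus"].young_modulus * I)
        top = mesh.node_sets["superior_plate"]
        slope = np.polyfit(mesh.nodes[top, 0], u[top, 1], 1)[0]
        assert -slope == pytest.approx(theta_ref, rel=0.02)

    def test_beam_surface_stress(self, beam_setup):
        geo, mats, mesh, load, u = beam_setup
        fld = fem.stress_fields(mesh, u, mats)
        m_line = 1000.0 * load.moment / load.out_of_plane_width
        I = geo.width**3 / 12.0
        mid = np.abs(fld.centroids[:, 1] - geo.height / 2) < 1.0
        x = fld.centroids[mid, 0]
        expected = -m_line * (x - geo.width / 2) / I
        np.testing.assert_allclose(fld.sigma_yy[mid], expected, rtol=0.02)

    def test_linearity_in_moment(self, beam_setup):
        geo, mats, mesh, load, u = beam_setup
        fld1 = fem.stress_fields(mesh, u, mats)
        load2 = LoadCase(moment=3.7 * load.moment, out_of_plane_width=load.out_of_plane_width)
        u2 = fem.solve_elasticity(mesh, mats, load2)
        fld2 = fem.stress_fields(mesh, u2, mats)
        np.testing.assert_allclose(fld2.sigma_yy, 3.7 * fld1.sigma_yy, rtol=1e-10, atol=1e-16)

    def test_moment_sign_flip_negates_axial_stress(self, beam_setup):
        geo, mats, mesh, load, u = beam_setup
        fld1 = fem.stress_fields(mesh, u, mats)
        u2 = fem.solve_elasticity(mesh, mats,
                                  LoadCase(moment=-load.moment,
                                           out_of_plane_width=load.out_of_plane_width))
        fld2 = fem.stress_fields(mesh, u2, mats)
        np.testing.assert_allclose(fld2.sigma_yy, -fld1.sigma_yy, rtol=1e-9, atol=1e-14)

    def test_principal_stress_ordering(self, beam_setup):
        geo, mats, mesh, load, u = beam_setup
        fld = fem.stress_fields(mesh, u, mats)
        assert np.all(fld.sigma_1 >= fld.sigma_2)
        assert np.all(fld.max_shear_intensity >= 0)

    def test_missing_constraint_raises(self):
        geo = DiscSectionGeometry(width=4.0, height=4.0, nucleus_x=(1.0, 3.0))
        mesh = fem.build_mesh(geo, 1.0)
        mesh.node_sets["inferior_plate"] = np.array([], dtype=int)
        with pytest.raises(ValueError, match="singular"):
            fem.solve_elasticity(mesh, homogeneous(), LoadCase(moment=1.0))


class TestGeometryFromLabels:
    def test_widths_consistent_with_boundary_extraction(self, intact_truth):
        lm = truth_labelmap(intact_truth)
        geo = fem.geometry_from_labels(lm, disc_height_mm=10.0)
        _, _, w = nucleus_boundaries(lm)
        xa, xp = geo.nucleus_x
        assert (xp - xa) == pytest.approx(w, abs=lm.pixel_spacing)
        assert geo.width == pytest.approx(2 * intact_truth.spec.disc_outer_semiaxes[0],
                                          abs=2 * lm.pixel_spacing)
        assert geo.notch is None

    def test_fissured_notch_dimensions(self, fissured_truth):
        lm = truth_labelmap(fissured_truth)
        meta = {"height_fraction": 0.54, "radial_fraction": 0.27}
        geo = fem.geometry_from_labels(lm, disc_height_mm=10.0, fissure_meta=meta)
        depth, ylo, yhi = geo.notch
        assert yhi - ylo == pytest.approx(5.4, abs=1e-9)
        assert depth == pytest.approx(0.27 * geo.nucleus_x[0], abs=1e-9)


class TestFissureComparison:
    def test_identical_fields_ratio_one(self, beam_setup):
        geo, mats, mesh, load, u = beam_setup
        fld = fem.stress_fields(mesh, u, mats)
        cmp = fem.compare_intact_fissured(fld, fld, (0.0, 2.0, 5.0, 15.0))
        assert cmp["ratio"]["shear_max"] == pytest.approx(1.0, abs=1e-12)

    def test_fissure_concentrates_shear(self, intact_truth, fissured_truth):
        """With disc materials and the bench extension moment, the fissured
        model's near-tip shear strictly exceeds the intact one."""
        from discqmri.pipeline import run_fem_comparison

        res = run_fem_comparison(labelmap_intact=truth_labelmap(intact_truth),
                                 labelmap_fissured=truth_labelmap(fissured_truth),
                                 moment=2.8, axial_force=59.7)
        s = res["summary"]
        assert s["fissured"]["shear_max"] > s["intact"]["shear_max"]
        assert s["fissured"]["axial_max"] > s["intact"]["axial_max"]

    def test_refinement_probe_mean_stable(self, intact_truth, fissured_truth):
        """The fissure-tip max grows on refinement (singular point) while the
        probe-region mean stays stable."""
        from discqmri.config import default_config
        from discqmri.pipeline import run_fem_comparison

        maxes, means = [], []
        for edge in (1.2, 0.6):
            cfg = default_config()
            cfg["fem"]["target_edge_mm"] = edge
            res = run_fem_comparison(cfg, labelmap_intact=truth_labelmap(intact_truth),
                                     labelmap_fissured=truth_labelmap(fissured_truth))
            maxes.append(res["summary"]["fissured"]["shear_max"])
            means.append(res["summary"]["fissured"]["shear_mean"])
        assert maxes[1] > maxes[0]
        assert means[1] == pytest.approx(means[0], rel=0.10)
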