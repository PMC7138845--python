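"""Mesh generation, fiber frames, and pouch geometry descriptors."""

import math

import numpy as np
import pytest

import colomech as cm
from colomech.constitutive import DomainError
from colomech.geometry_factory import (
    PouchSpec,
    _sdf_and_grad,
    build_normal_mesh,
    build_pouch_mesh,
    pouch_geometry_metrics,
    reflect_mesh_z,
    write_vtk,
)

GRID = [(h, d) for h in (2.0, 4.0, 6.0) for d in (8.0, 10.0, 12.0)]


class TestNormalMesh:
    def test_total_area_closed_form(self, geom):
        # half circumference x half length: A = pi * Rm * L / 2
        mesh = build_normal_mesh(geom, 1.3)
        expected = math.pi * geom.r_mid * geom.length_axial / 2
        assert mesh.areas().sum() == pytest.approx(expected, rel=5e-3)

    def test_element_areas_bounded(self, geom):
        mesh = build_normal_mesh(geom, 1.3)
        areas = mesh.areas()
        assert areas.max() < 2.0 * 1.3**2
        assert areas.min() > 1.3**2 / 8.0

    def test_refinement_quadruples_count(self, geom):
        n1 = build_normal_mesh(geom, 2.0).n_cells
        n2 = build_normal_mesh(geom, 1.0).n_cells
        assert n2 == pytest.approx(4 * n1, rel=0.1)

    def test_normals_outward(self, geom):
        mesh = build_normal_mesh(geom, 2.0)
        cent = mesh.centroids()
        radial = cent.copy()
        radial[:, 2] = 0.0
        assert np.all(np.einsum("ij,ij->i", mesh.normals, radial) > 0.0)

    def test_oversized_mesh_size_rejected(self, geom):
        with pytest.raises(DomainError):
            build_normal_mesh(geom, 60.0)

    def test_symmetry_tags(self, geom):
        mesh = build_normal_mesh(geom, 2.0)
        tags = mesh.node_tags
        assert np.allclose(mesh.nodes[tags["sym_yz"], 0], 0.0, atol=1e-9)
        assert np.allclose(mesh.nodes[tags["sym_xy"], 2], 0.0, atol=1e-9)
        assert np.allclose(mesh.nodes[tags["far_end"], 2], 50.0, atol=1e-9)


class TestPouchMesh:
    @pytest.mark.parametrize("h,d", [(4.0, 10.0), (6.0, 8.0), (2.0, 12.0)])
    def test_nodes_on_implicit_surface(self, geom, h, d):
        spec = PouchSpec(d, h)
        mesh = build_pouch_mesh(geom, spec, 1.3)
        phi, _ = _sdf_and_grad(mesh.nodes, geom, spec)
        assert np.abs(phi).max() < max(1.3, 0.1)
        # construction actually lands on the surface to projection tolerance
        assert np.abs(phi).max() < 1e-3

    def test_apex_height(self, geom):
        mesh = build_pouch_mesh(geom, PouchSpec(10.0, 4.0), 1.3)
        r = np.linalg.norm(mesh.nodes[:, :2], axis=1)
        assert r.max() == pytest.approx(geom.r_mid + 4.0, rel=0.01)

    def test_fillet_zero_area_matches_union_oracle(self, geom):
        # rf -> 0: mesh area -> quarter cylinder - neck-base/4 + pouch cap/4,
        # with the base/cap areas from the semi-analytic metric quadratures
        spec = PouchSpec(10.0, 4.0, fillet_radius=1e-6)
        mesh = build_pouch_mesh(geom, spec, 1.0)
        m = pouch_geometry_metrics(geom, spec)
        expected = (
            math.pi * geom.r_mid * geom.length_axial / 2
            - m.a_b / 4.0 + m.s_p / 4.0
        )
        assert mesh.areas().sum() == pytest.approx(expected, rel=0.02)

    def test_pouch_region_tagged(self, geom):
        mesh = build_pouch_mesh(geom, PouchSpec(10.0, 4.0), 1.3)
        assert mesh.node_tags["pouch_region"].any()
        lifted = np.linalg.norm(mesh.nodes[:, :2], axis=1) > geom.r_mid + 0.5
        assert mesh.node_tags["pouch_region"][lifted].all()

    def test_swallowed_sphere_rejected(self, geom):
        with pytest.raises(DomainError):
            PouchSpec(10.0, 12.0)  # H >= D: not a proper cap


class TestFiberFrame:
    def test_cylinder_frame_exact(self, geom):
        mesh = build_normal_mesh(geom, 2.0)
        assert np.allclose(mesh.fiber_long, [0.0, 0.0, 1.0], atol=1e-12)
        hoop = np.abs(np.einsum("ij,ij->i", mesh.fiber_circ, mesh.normals))
        assert hoop.max() < 1e-12
        assert np.allclose(np.linalg.norm(mesh.fiber_circ, axis=1), 1.0)

    def test_orthonormal_tangent_everywhere(self, coarse_pouch):
        m = coarse_pouch
        assert np.abs(np.einsum("ij,ij->i", m.fiber_long, m.normals)).max() < 1e-10
        assert np.abs(np.einsum("ij,ij->i", m.fiber_circ, m.normals)).max() < 1e-10
        assert np.abs(np.einsum("ij,ij->i", m.fiber_circ, m.fiber_long)).max() < 1e-10
        assert np.allclose(np.linalg.norm(m.fiber_long, axis=1), 1.0)

    def test_apex_frame_orientation(self, geom):
        mesh = build_pouch_mesh(geom, PouchSpec(10.0, 4.0), 1.3)
        cent = mesh.centroids()
        apex = mesh.meta["apex"]
        k = int(np.argmin(np.linalg.norm(cent - apex, axis=1)))
        # normal ~ +y there: longitudinal ~ z, circumferential ~ +/- x
        assert abs(mesh.fiber_long[k, 2]) > 0.99
        assert abs(mesh.fiber_circ[k, 0]) > 0.99


class TestPouchMetrics:
    def test_flat_surface_limit_closed_forms(self):
        big = cm.TubeGeometry(r_inner=1e5 - 0.6, r_outer=1e5 + 0.6)
        m = pouch_geometry_metrics(big, PouchSpec(10.0, 4.0))
        w = 2.0 * math.sqrt(4.0 * (10.0 - 4.0))
        assert m.d_z == pytest.approx(w, rel=1e-6)
        assert m.d_x == pytest.approx(w, rel=1e-3)
        assert m.s_p == pytest.approx(math.pi * 10.0 * 4.0, rel=1e-3)
        assert m.a_b == pytest.approx(math.pi * 4.0 * (10.0 - 4.0), rel=1e-3)

    def test_dz_closed_form_exact_on_cylinder(self, geom):
        # the cylinder is straight along z, so Dz keeps the spherical-cap
        # chord value exactly
        m = pouch_geometry_metrics(geom, PouchSpec(10.0, 4.0))
        assert m.d_z == pytest.approx(2.0 * math.sqrt(24.0), rel=1e-12)
        assert m.d_x > m.d_z  # curvature widens the x chord

    def test_tangent_sphere_degenerates_to_zero(self, geom):
        m = pouch_geometry_metrics(geom, PouchSpec(10.0, 1e-12))
        assert abs(m.d_x) < 1e-4 and abs(m.d_z) < 1e-4
        assert abs(m.a_b) < 1e-4 and abs(m.s_p) < 1e-4

    def test_monotonicity_over_study_grid(self, geom):
        # neck measures grow with H only up to the hemisphere (H = D/2):
        # d_z = 2 sqrt(H (D - H)) peaks there and shrinks for taller caps.
        # s_p (the pouch surface itself) always grows with H; everything
        # grows with D at fixed H.
        vals = {
            (h, d): pouch_geometry_metrics(geom, PouchSpec(d, h))
            for h, d in GRID
        }
        for d in (8.0, 10.0, 12.0):
            for h0, h1 in ((2.0, 4.0), (4.0, 6.0)):
                a, b = vals[(h0, d)], vals[(h1, d)]
                assert b.s_p > a.s_p
                if h1 <= d / 2.0:
                    assert b.d_z > a.d_z and b.a_b > a.a_b
                elif h0 >= d / 2.0:
                    assert b.d_z < a.d_z and b.a_b < a.a_b
        for h in (2.0, 4.0, 6.0):
            for d0, d1 in ((8.0, 10.0), (10.0, 12.0)):
                a, b = vals[(h, d0)], vals[(h, d1)]
                assert b.d_x > a.d_x and b.d_z > a.d_z
                assert b.a_b > a.a_b and b.s_p > a.s_p

    def test_discrete_area_converges_to_quadrature(self, geom):
        # a_b + s_p from the mesh (pre-fillet) vs the semi-analytic values
        spec = PouchSpec(10.0, 4.0, fillet_radius=1e-6)
        m = pouch_geometry_metrics(geom, spec)
        mesh = build_pouch_mesh(geom, spec, 1.0)
        lifted = np.linalg.norm(mesh.centroids()[:, :2], axis=1) > geom.r_mid + 0.05
        cap_area = mesh.areas()[lifted].sum() * 4.0
        assert cap_area == pytest.approx(m.s_p, rel=0.05)


class TestReflect:
    def test_half_model_doubles_quarter(self, coarse_pouch):
        half = reflect_mesh_z(coarse_pouch)
        assert half.n_cells == 2 * coarse_pouch.n_cells
        assert half.areas().sum() == pytest.approx(
            2 * coarse_pouch.areas().sum(), rel=1e-9
        )
        assert not half.node_tags["sym_xy"].any()
        assert half.node_tags["far_end"].sum() == 2 * coarse_pouch.node_tags[
            "far_end"
        ].sum()


class TestVtkExport:
    def test_written_file_is_consistent(self, tmp_path, coarse_cylinder):
        path = tmp_path / "mesh.vtk"
        write_vtk(coarse_cylinder, path, cell_data={"ones": np.ones(
            coarse_cylinder.n_cells)})
        text = path.read_text().splitlines()
        assert text[0].startswith("# vtk DataFile")
        assert f"POINTS {coarse_cylinder.n_nodes} double" in text
        assert f"CELL_TYPES {coarse_cylinder.n_cells}" in text
        assert any(line.startswith("VECTORS fiber_long") for line in text)
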