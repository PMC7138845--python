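"""Membrane finite-element solver: kinematics, tangent, and oracles."""

import numpy as np
import pytest

import colomech as cm
from colomech.geometry_factory import build_normal_mesh, build_pouch_mesh, reflect_mesh_z
from colomech.membrane_fe import (
    LoadSchedule,
    _Assembler,
    _Constraints,
    mesh_convergence_study,
    solve_sweep,
)


class TestLoadSchedule:
    def test_defaults_match_protocol(self):
        loads = LoadSchedule()
        assert loads.axial_prestretch == 1.10
        assert loads.pressure_max_kpa == 5.0
        assert loads.pressure_step_kpa == 0.25
        assert len(loads.levels_kpa) == 21

    def test_step_must_divide_max(self):
        with pytest.raises(Exception):
            LoadSchedule(pressure_max_kpa=5.0, pressure_step_kpa=0.3)


class TestHomogeneousStates:
    def test_pure_prestretch_is_exactly_homogeneous(self, coarse_cylinder, set1):
        sweep = solve_sweep(
            coarse_cylinder, set1,
            LoadSchedule(pressure_max_kpa=0.0, pressure_step_kpa=0.25),
        )
        f = sweep.fields[-1]
        assert np.allclose(f.stretches[:, 1], 1.10, atol=1e-6)
        for col in range(2):
            sig = f.stress[:, col]
            assert sig.std() <= 1e-6 * max(abs(sig.mean()), 1.0)

    def test_incompressibility_by_construction(self, coarse_cylinder, set1):
        sweep = solve_sweep(
            coarse_cylinder, set1,
            LoadSchedule(pressure_max_kpa=1.0, pressure_step_kpa=0.5),
        )
        f = sweep.fields[-1]
        lam_t = 1.0 / (f.stretches[:, 0] * f.stretches[:, 1])
        assert np.allclose(f.stretches[:, 0] * f.stretches[:, 1] * lam_t, 1.0,
                           atol=1e-12)


class TestAnalyticOracle:
    def test_cylinder_matches_closed_form_within_1_percent(self, geom, set1):
        mesh = build_normal_mesh(geom, 2.5)
        sweep = solve_sweep(mesh, set1, LoadSchedule(pressure_max_kpa=5.0,
                                                     pressure_step_kpa=0.5))
        for lv, f in zip(sweep.levels_kpa, sweep.fields):
            lam_fe = f.stretches[:, 0].mean()
            lam_an = cm.solve_inflation(set1, lv * 1e3, 1.1, geom)
            assert lam_fe == pytest.approx(lam_an, rel=0.01)

    def test_validation_r2_near_one(self, geom, set1):
        mesh = build_normal_mesh(geom, 2.5)
        sweep = solve_sweep(mesh, set1, LoadSchedule(pressure_max_kpa=5.0,
                                                     pressure_step_kpa=0.5))
        rep = cm.validate_normal_model(sweep, set1, geom)
        assert rep.r2_axial > 0.999
        assert rep.r2_circ > 0.999


class TestRigidBody:
    def test_cylinder(self, coarse_cylinder, set1):
        assert cm.rigid_body_check(coarse_cylinder, set1)

    def test_pouch(self, coarse_pouch, set1):
        assert cm.rigid_body_check(coarse_pouch, set1)


class TestConsistentTangent:
    def test_stiffness_matches_residual_differences(self, geom, set1, rng):
        """K * delta == central difference of the residual, including the
        unsymmetric follower-pressure load stiffness."""
        mesh = build_normal_mesh(geom, 10.0)
        asm = _Assembler(mesh, set1)
        X = asm.X.reshape(-1)
        u = 1e-4 * rng.standard_normal(asm.ndof)
        P = 500.0
        out = asm.residual((X + u).reshape(-1, 3), P, with_K=True)
        R0, _, K = out
        h = 1e-8
        delta = rng.standard_normal(asm.ndof)
        delta /= np.linalg.norm(delta)
        Rp = asm.residual((X + u + h * delta).reshape(-1, 3), P, with_K=False)[0]
        Rm = asm.residual((X + u - h * delta).reshape(-1, 3), P, with_K=False)[0]
        fd = (Rp - Rm) / (2 * h)
        Kd = K @ delta
        denom = max(np.linalg.norm(fd), 1e-12)
        assert np.linalg.norm(Kd - fd) / denom < 1e-5

    def test_internal_forces_are_energy_gradient(self, geom, set1, rng):
        mesh = build_normal_mesh(geom, 10.0)
        asm = _Assembler(mesh, set1)
        X = asm.X.reshape(-1)
        u = 1e-4 * rng.standard_normal(asm.ndof)
        d, F, C = asm.deformation((X + u).reshape(-1, 3))
        S, _ = asm._stress(C, with_tangent=False)
        g = asm.internal_forces(F, S)
        h = 1e-7
        delta = rng.standard_normal(asm.ndof)
        delta /= np.linalg.norm(delta)
        ep = asm.energy((X + u + h * delta).reshape(-1, 3))
        em = asm.energy((X + u - h * delta).reshape(-1, 3))
        assert g @ delta == pytest.approx((ep - em) / (2 * h), rel=2e-5)


class TestSymmetry:
    def test_half_model_mirror_pairs_agree(self, geom, set1):
        quarter = build_pouch_mesh(geom, cm.PouchSpec(10.0, 4.0), 3.0)
        half = reflect_mesh_z(quarter)
        loads = LoadSchedule(pressure_max_kpa=0.5, pressure_step_kpa=0.25)
        sq = solve_sweep(quarter, set1, loads)
        sh = solve_sweep(half, set1, loads)
        fq = sq.field_at(0.5)
        fh = sh.field_at(0.5)
        m = quarter.n_cells
        # mirrored element block repeats the originals in order
        assert np.allclose(fh.sigma_mps[m:], fh.sigma_mps[:m], rtol=5e-5)
        # and the half model agrees with the quarter model
        assert np.allclose(fh.sigma_mps[:m], fq.sigma_mps, rtol=1e-3)

    def test_pinned_null_mode_carries_no_reaction(self, geom, set1):
        mesh = build_normal_mesh(geom, 4.0)
        loads = LoadSchedule(pressure_max_kpa=0.5, pressure_step_kpa=0.25)
        sweep = solve_sweep(mesh, set1, loads, store_displacements=True)
        con = _Constraints(mesh, loads)
        asm = _Assembler(mesh, set1)
        x = mesh.nodes * 1e-3 + sweep.displacements[-1] * 1e-3
        R, scale, _ = asm.residual(x, 500.0, with_K=False)
        # residual at the pinned y dof (a reaction row) is at solver tolerance
        assert abs(R[3 * con.pin_node + 1]) <= 1e-6 * scale


class TestConvergenceStudy:
    def test_large_tolerance_stops_after_first_refinement(self, geom, set1):
        loads = LoadSchedule(pressure_max_kpa=1.0, pressure_step_kpa=0.5)
        chosen, table = mesh_convergence_study(
            lambda s: build_normal_mesh(geom, s), set1, loads,
            tol_percent=100.0, start_size=4.0,
        )
        assert chosen == 4.0
        assert len(table) == 2

    def test_variation_decreases_under_refinement(self, geom, set1):
        loads = LoadSchedule(pressure_max_kpa=1.0, pressure_step_kpa=0.5)
        sizes = [4.0, 2.0, 1.0]
        vals = []
        for s in sizes:
            sweep = solve_sweep(build_normal_mesh(geom, s), set1, loads)
            vals.append(sweep.fields[-1].sigma_mps.max())
        v1 = abs(vals[1] - vals[0]) / vals[0]
        v2 = abs(vals[2] - vals[1]) / vals[1]
        assert v2 < v1

    def test_converged_peak_matches_thin_wall_analytic(self, geom, set1):
        loads = LoadSchedule(pressure_max_kpa=1.0, pressure_step_kpa=0.5)
        sweep = solve_sweep(build_normal_mesh(geom, 1.3), set1, loads)
        lam = cm.solve_inflation(set1, 1000.0, 1.1, geom)
        sig_t, sig_z = cm.isochoric_stresses(set1, cm.StretchState(lam, 1.1))
        expected = max(sig_t, sig_z, 0.0)
        assert sweep.fields[-1].sigma_mps.max() == pytest.approx(expected, rel=0.03)


class TestDeterminism:
    def test_identical_reruns_bit_identical(self, geom, set1):
        mesh = build_normal_mesh(geom, 4.0)
        loads = LoadSchedule(pressure_max_kpa=0.5, pressure_step_kpa=0.25)
        a = solve_sweep(mesh, set1, loads)
        b = solve_sweep(mesh, set1, loads)
        for fa, fb in zip(a.fields, b.fields):
            assert np.array_equal(fa.sigma_mps, fb.sigma_mps)


class TestFieldExport:
    def test_vtk_and_summary_written_per_level(self, tmp_path, coarse_cylinder,
                                               set1):
        from colomech.membrane_fe import export_sweep_fields

        loads = LoadSchedule(pressure_max_kpa=0.5, pressure_step_kpa=0.25)
        sweep = solve_sweep(coarse_cylinder, set1, loads,
                            store_displacements=True)
        paths = export_sweep_fields(sweep, tmp_path)
        vtks = [p for p in paths if p.suffix == ".vtk"]
        assert len(vtks) == len(sweep.levels_kpa)
        text = vtks[-1].read_text()
        assert "sigma_mps" in text and "displacement_mm" in text
        import pandas as pd

        summary = pd.read_csv(tmp_path / "sweep_summary.csv")
        assert list(summary.columns) == ["pressure_kPa", "max_sigma_mps_Pa",
                                         "newton_iters"]
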