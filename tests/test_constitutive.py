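"""Constitutive model: invariants, energy, stresses, and their derivatives."""

import dataclasses
import math

import numpy as np
import pytest
import sympy as sp

import colomech as cm
from colomech.constitutive import (
    DomainError,
    RangeOverflowError,
    membrane_stress_tangent,
)

from conftest import admissible_states


def sympy_energy_and_derivs(p):
    """Symbolic oracle: W(I1, I4l, I4s) and all partials, built independently
    of the implementation from the model formula."""
    i1, i4l, i4s = sp.symbols("i1 i4l i4s", positive=True)
    W = (
        p.c10 * (i1 - 3)
        + p.k1_l / p.k2_l * (sp.exp(p.k2_l * (i4l - 1) ** 2) - 1)
        + p.k1_s / p.k2_s * (sp.exp(p.k2_s * (i4s - 1) ** 2) - 1)
    )
    syms = (i1, i4l, i4s)
    first = [sp.lambdify(syms, sp.diff(W, s)) for s in syms]
    second = [[sp.lambdify(syms, sp.diff(W, a, b)) for b in syms] for a in syms]
    return sp.lambdify(syms, W), first, second


class TestInvariants:
    def test_identity(self):
        inv = cm.invariants(cm.StretchState(1.0, 1.0), 30.0)
        assert inv.i1 == pytest.approx(3.0)
        assert inv.i4_l == pytest.approx(1.0)
        assert inv.i4_s == pytest.approx(1.0)

    def test_printed_formula_arithmetic(self):
        inv = cm.invariants(cm.StretchState(1.2, 1.1), 44.0)
        assert inv.i1 == pytest.approx(1.44 + 1.21 + 1 / 1.7424, rel=1e-12)
        expected_i4s = 1.44 * math.cos(math.radians(44)) ** 2 \
            + 1.21 * math.sin(math.radians(44)) ** 2
        assert inv.i4_s == pytest.approx(expected_i4s, rel=1e-12)
        assert inv.i4_s == pytest.approx(1.3290, abs=5e-5)
        assert inv.i4_l == pytest.approx(1.21)

    def test_i1_lower_bound(self, rng):
        for st in admissible_states(rng, 50, 0.7, 1.4):
            assert cm.invariants(st, 45.0).i1 >= 3.0 - 1e-12

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(DomainError):
            cm.StretchState(0.0, 1.0)
        with pytest.raises(DomainError):
            cm.StretchState(1.0, -2.0)

    def test_gamma_sign_symmetry(self, rng):
        for st in admissible_states(rng, 10, 0.9, 1.2):
            a = cm.invariants(st, 44.0)
            b = cm.invariants(st, -44.0)
            assert a.i4_s == pytest.approx(b.i4_s, rel=1e-14)


class TestMaterialParams:
    def test_packaged_sets_as_printed(self, material_sets):
        assert [p.label for p in material_sets] == ["#1", "#2", "#3", "#4", "#5"]
        p1 = material_sets[0]
        assert (p1.c10, p1.k1_l, p1.k2_l) == (411.0, 1416.0, 80.63)
        assert (p1.k1_s, p1.k2_s, p1.gamma_s) == (30.0, 164.22, 44.0)
        p5 = material_sets[4]
        assert (p5.c10, p5.k1_l, p5.k2_l) == (1591.0, 150.0, 1.15)
        assert (p5.k1_s, p5.k2_s, p5.gamma_s) == (439.0, 39.82, 49.0)

    def test_invalid_values_rejected(self, set1):
        with pytest.raises(DomainError):
            dataclasses.replace(set1, c10=-1.0)
        with pytest.raises(DomainError):
            dataclasses.replace(set1, k2_l=0.0)
        with pytest.raises(DomainError):
            dataclasses.replace(set1, gamma_s=120.0)


class TestStrainEnergy:
    def test_zero_at_identity_all_sets(self, material_sets):
        for p in material_sets:
            assert cm.strain_energy(p, cm.StretchState(1, 1)) == pytest.approx(0.0)

    def test_neo_hookean_reduction(self, set1):
        nh = dataclasses.replace(set1, k1_l=0.0, k1_s=0.0)
        w = cm.strain_energy(nh, cm.StretchState(1.2, 1.1))
        assert w == pytest.approx(411.0 * (1.44 + 1.21 + 1 / 1.7424 - 3), rel=1e-12)
        assert w == pytest.approx(92.0, abs=0.1)

    def test_matches_symbolic_oracle(self, material_sets, rng):
        for p in material_sets:
            W, _, _ = sympy_energy_and_derivs(p)
            for st in admissible_states(rng, 10):
                inv = cm.invariants(st, p.gamma_s)
                # expm1 in the implementation vs exp()-1 in the oracle
                assert cm.strain_energy(p, st) == pytest.approx(
                    float(W(inv.i1, inv.i4_l, inv.i4_s)), rel=1e-9, abs=1e-9
                )

    def test_positive_away_from_identity(self, material_sets, rng):
        for p in material_sets:
            for st in admissible_states(rng, 20):
                if abs(st.lambda_theta - 1) + abs(st.lambda_z - 1) > 1e-3:
                    assert cm.strain_energy(p, st) > 0.0

    def test_monotone_fiber_recruitment(self, material_sets):
        # loading ray: W non-decreasing in lambda_theta >= 1 at fixed lambda_z
        for p in material_sets:
            for lz in (1.0, 1.05):
                lams = np.linspace(1.0, 1.12, 25)
                ws = [cm.strain_energy(p, cm.StretchState(lt, lz)) for lt in lams]
                assert np.all(np.diff(ws) >= -1e-12)

    def test_overflow_is_range_error(self, set1):
        with pytest.raises(RangeOverflowError):
            cm.strain_energy(set1, cm.StretchState(3.0, 3.0))


class TestEnergyDerivatives:
    def test_dI1_is_c10_and_fiber_zero_at_one(self, material_sets):
        for p in material_sets:
            d = cm.energy_derivatives(p, cm.InvariantSet(3.7, 1.0, 1.0))
            assert d.first[0] == pytest.approx(p.c10)
            assert d.first[1] == 0.0
            assert d.first[2] == 0.0

    def test_k1_zero_kills_term(self, set1):
        p = dataclasses.replace(set1, k1_l=0.0)
        d = cm.energy_derivatives(p, cm.InvariantSet(3.2, 1.3, 1.1))
        assert d.first[1] == 0.0
        assert d.second[1, 1] == 0.0

    def test_all_partials_match_symbolic_oracle(self, material_sets, rng):
        for p in material_sets:
            _, first, second = sympy_energy_and_derivs(p)
            for st in admissible_states(rng, 20):
                inv = cm.invariants(st, p.gamma_s)
                args = (inv.i1, inv.i4_l, inv.i4_s)
                d = cm.energy_derivatives(p, inv)
                for k in range(3):
                    assert d.first[k] == pytest.approx(
                        float(first[k](*args)), rel=1e-10, abs=1e-12
                    )
                for a in range(3):
                    for b in range(3):
                        assert d.second[a, b] == pytest.approx(
                            float(second[a][b](*args)), rel=1e-10, abs=1e-12
                        )
                assert np.allclose(d.second, d.second.T)


class TestIsochoricStresses:
    def test_zero_at_identity(self, material_sets):
        for p in material_sets:
            st, sz = cm.isochoric_stresses(p, cm.StretchState(1, 1))
            assert st == pytest.approx(0.0, abs=1e-10)
            assert sz == pytest.approx(0.0, abs=1e-10)

    def test_neo_hookean_hand_value(self, set1):
        nh = dataclasses.replace(set1, k1_l=0.0, k1_s=0.0)
        st, _ = cm.isochoric_stresses(nh, cm.StretchState(1.2, 1.1))
        assert st == pytest.approx(411.0 * (2 * 1.44 - 2 / 1.7424), rel=1e-12)
        assert st == pytest.approx(712.0, abs=1.0)

    @pytest.mark.parametrize("iset", range(5))
    def test_matches_stretch_finite_differences(self, material_sets, iset, rng):
        # sigma = lambda dW/dlambda, checked against central differences of
        # the energy in each stretch (the spec's finite-difference oracle)
        p = material_sets[iset]
        h = 1e-6
        for st in admissible_states(rng, 100):
            lt, lz = st.lambda_theta, st.lambda_z
            sig_t, sig_z = cm.isochoric_stresses(p, st)
            fd_t = lt * (
                cm.strain_energy(p, cm.StretchState(lt + h, lz))
                - cm.strain_energy(p, cm.StretchState(lt - h, lz))
            ) / (2 * h)
            fd_z = lz * (
                cm.strain_energy(p, cm.StretchState(lt, lz + h))
                - cm.strain_energy(p, cm.StretchState(lt, lz - h))
            ) / (2 * h)
            assert sig_t == pytest.approx(fd_t, rel=1e-6, abs=1e-4)
            assert sig_z == pytest.approx(fd_z, rel=1e-6, abs=1e-4)


class TestMembraneCauchy:
    def test_identity_zero(self, material_sets):
        for p in material_sets:
            sig = cm.membrane_cauchy(p, np.eye(2))
            assert np.allclose(sig, 0.0, atol=1e-10)

    def test_diagonal_consistency_with_isochoric(self, material_sets):
        for p in material_sets:
            U = np.diag([1.05, 1.04])
            sig = cm.membrane_cauchy(p, U)
            st, sz = cm.isochoric_stresses(p, cm.StretchState(1.05, 1.04))
            assert sig[0, 0] == pytest.approx(st, rel=1e-10)
            assert sig[1, 1] == pytest.approx(sz, rel=1e-10)
            assert sig[0, 1] == pytest.approx(0.0, abs=1e-8)

    def test_objectivity_under_frame_rotation(self, set1):
        ang = 0.35
        Q = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        U = np.diag([1.05, 1.03])
        sig = cm.membrane_cauchy(set1, U)
        sig_rot = cm.membrane_cauchy(set1, Q @ U @ Q.T, fiber_axes=Q)
        assert np.allclose(sig_rot, Q @ sig @ Q.T, rtol=1e-10, atol=1e-8)

    def test_non_spd_rejected(self, set1):
        with pytest.raises(DomainError):
            cm.membrane_cauchy(set1, np.array([[1.0, 0.2], [0.1, 1.0]]))
        with pytest.raises(DomainError):
            cm.membrane_cauchy(set1, np.diag([-1.0, 1.0]))

    def test_batch_tangent_matches_fd(self, set1, rng):
        # dS/dC of the plane-stress condensation vs central differences
        C = np.array([[1.08, 0.015], [0.015, 1.05]])
        S0, dSdC = membrane_stress_tangent(set1, C[None])
        h = 1e-7
        for a in range(2):
            for b in range(2):
                dC = np.zeros((2, 2))
                dC[a, b] += 0.5 * h
                dC[b, a] += 0.5 * h
                Sp, _ = membrane_stress_tangent(set1, (C + dC)[None],
                                                with_tangent=False)
                Sm, _ = membrane_stress_tangent(set1, (C - dC)[None],
                                                with_tangent=False)
                fd = (Sp[0] - Sm[0]) / (2 * h)
                sym_tan = 0.5 * (dSdC[0, :, :, a, b] + dSdC[0, :, :, b, a])
                assert np.allclose(sym_tan, fd, rtol=2e-6, atol=1e-3)
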