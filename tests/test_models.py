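"""Unit and property tests for the insulin-kinetics / glucose-PD models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from practident import (
    NGT,
    GlucosePDParams,
    InsulinKineticParams,
    SecretionProfile,
    StateVector,
    basal_steady_state,
    combined_clearance,
    glucose_rhs,
    insulin_rhs,
)


def kin(**over):
    base = dict(nK=0.054, nL=0.218, nC=0.03, nI=0.3, alphaI=0.001, xL=0.797, VP=4.0, VQ=8.0)
    base.update(over)
    return InsulinKineticParams(**base)


class TestValidation:
    @pytest.mark.parametrize(
        "field,value",
        [("VP", -1.0), ("VP", 0.0), ("VQ", -2.0), ("nK", -0.1), ("alphaI", -0.01), ("xL", 1.5)],
    )
    def test_insulin_params_reject_invalid(self, field, value):
        with pytest.raises(ValueError):
            kin(**{field: value})

    @pytest.mark.parametrize("field,value", [("VG", 0.0), ("pG", -0.1), ("Gb", 0.0)])
    def test_glucose_params_reject_invalid(self, field, value):
        base = dict(pG=0.02, SI=2e-3, VG=9.75, Gb=5.0, Qb=2.0)
        base.update({field: value})
        with pytest.raises(ValueError):
            GlucosePDParams(**base)


class TestInsulinRhs:
    def test_basal_steady_state_is_equilibrium(self):
        sec = NGT.secretion
        basal = basal_steady_state(NGT.kin, sec, NGT.pd)
        dI, dQ = insulin_rhs(basal, 0.0, NGT.kin, sec)
        assert abs(dI) < 1e-10 and abs(dQ) < 1e-10

    def test_saturation_free_limit_is_linear_clearance(self):
        k = kin(alphaI=0.0)
        state = StateVector(I=123.0, Q=0.0, G=5.0)
        sec = SecretionProfile(0.0, 0.0, 0.0)
        dI, _ = insulin_rhs(state, 0.0, k, sec)
        # hepatic term reduces to -nL*I exactly; remove the other known terms
        hepatic = dI + k.nK * 123.0 + (k.nI / k.VP) * 123.0
        assert hepatic == pytest.approx(-k.nL * 123.0, rel=1e-12)

    def test_saturation_denominator_ratio(self):
        # at I = 100 mU/L the hepatic terms under alphaI = 0.05 vs 0.001
        # differ exactly by the ratio of the saturation denominators
        sec = SecretionProfile(0.0, 0.0, 0.0)
        state = StateVector(I=100.0, Q=100.0, G=5.0)  # Q=I kills the exchange term

        def hepatic(alpha):
            k = kin(alphaI=alpha, nK=0.0)
            dI, _ = insulin_rhs(state, 0.0, k, sec)
            return dI

        assert hepatic(0.05) / hepatic(0.001) == pytest.approx((1 + 0.1) / (1 + 5.0), rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        I1=st.floats(0.1, 500.0),
        I2=st.floats(0.1, 500.0),
        alpha=st.floats(1e-4, 0.1),
        nL=st.floats(0.01, 0.5),
    )
    def test_hepatic_clearance_monotone_and_bounded(self, I1, I2, alpha, nL):
        lo, hi = sorted((I1, I2))
        f = lambda I: nL * I / (1.0 + alpha * I)
        assert f(hi) >= f(lo)
        assert f(hi) <= nL / alpha + 1e-12


class TestGlucoseRhs:
    def test_basal_equilibrium(self):
        dG = glucose_rhs(StateVector(I=0, Q=NGT.pd.Qb, G=NGT.pd.Gb), 0.0, NGT.pd)
        assert dG == pytest.approx(0.0, abs=1e-14)

    def test_relaxation_toward_basal_from_below(self):
        pd = NGT.pd.with_(SI=0.0)
        dG = glucose_rhs(StateVector(I=0, Q=pd.Qb, G=pd.Gb - 1.0), 0.0, pd)
        assert dG > 0

    def test_hand_computed_value(self):
        # direct arithmetic oracle on the NGT parameter set
        pd = NGT.pd
        G, Q = 8.0, 2.0 * pd.Qb
        expected = -pd.pG * (G - pd.Gb) - pd.SI * (G * Q - pd.Gb * pd.Qb)
        assert glucose_rhs(StateVector(I=0, Q=Q, G=G), 0.0, pd) == pytest.approx(expected)

    @settings(max_examples=30, deadline=None)
    @given(si1=st.floats(1e-5, 5e-3), si2=st.floats(1e-5, 5e-3))
    def test_dG_monotone_decreasing_in_SI_above_basal(self, si1, si2):
        lo, hi = sorted((si1, si2))
        pd_lo, pd_hi = NGT.pd.with_(SI=lo), NGT.pd.with_(SI=hi)
        state = StateVector(I=0, Q=3 * NGT.pd.Qb, G=8.0)  # G*Q > Gb*Qb
        assert glucose_rhs(state, 0.0, pd_hi) <= glucose_rhs(state, 0.0, pd_lo)


class TestCombinedClearance:
    def test_sums_clearances_and_removes_saturation(self):
        k = kin(nL=0.218, nK=0.06)
        c = combined_clearance(k)
        assert c.nL == pytest.approx(0.278)
        assert c.nK == 0.0 and c.alphaI == 0.0

    def test_zero_rates(self):
        c = combined_clearance(kin(nL=0.0, nK=0.0))
        assert c.nL == 0.0

    def test_documented_default_nT(self):
        c = combined_clearance(NGT.kin)
        assert c.nL == pytest.approx(NGT.kin.nK + 0.218)


class TestBasalSteadyState:
    def test_zero_secretion_gives_zero_insulin(self):
        ss = basal_steady_state(kin(), SecretionProfile(0.0, 0.0, 0.0), NGT.pd)
        assert ss.I == 0.0 and ss.Q == 0.0

    def test_matches_long_horizon_relaxation(self):
        # independent oracle: relax the ODE for 10,000 min with solve_ivp
        k, sec, pd = NGT.kin, NGT.secretion, NGT.pd

        def rhs(t, y):
            return insulin_rhs(StateVector(y[0], y[1], pd.Gb), 0.0, k,
                               SecretionProfile(sec.Ub, sec.Ub, sec.Ub))

        sol = solve_ivp(rhs, (0, 10_000), [50.0, 0.0], rtol=1e-10, atol=1e-12)
        ss = basal_steady_state(k, sec, pd)
        assert sol.y[0, -1] == pytest.approx(ss.I, rel=1e-6)
        assert sol.y[1, -1] == pytest.approx(ss.Q, rel=1e-6)
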