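import math

import numpy as np
import pytest

from sfekin import (
    BicParams,
    EquilibriumParams,
    ModelParams,
    approx_lumped_curve,
    bic_curve,
    bic_equivalent_ti,
    cell_opening_balance,
    constant_rate_period,
    dominant_time_constant,
    inaccessible_fraction,
    tc_shift_for_K,
    yield_at,
    ys_shift_mixer,
    ys_shift_plug,
)


class TestSlopeCompensation:
    def test_plug_identity_and_saturated_limit(self):
        assert ys_shift_plug(0.01, 0.7, 0.7, 2.0) == 0.01
        # tr >> tc both ways: the saturated outlet pins ys uniquely
        assert ys_shift_plug(0.01, 0.02, 0.04, 50.0) == pytest.approx(0.01, rel=1e-6)

    def test_plug_worked_ratio(self):
        # (1 - e^-1)/(1 - e^-0.5)
        expected = (1 - math.exp(-1.0)) / (1 - math.exp(-0.5))
        assert ys_shift_plug(1.0, 1.0, 2.0, 1.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.6065, rel=1e-4)

    def test_mixer_worked_ratio(self):
        assert ys_shift_mixer(1.0, 0.3, 0.45, 2.35) == pytest.approx(2.80 / 2.65, rel=1e-12)

    def test_mixer_shift_preserves_period1_slope_in_simulation(self):
        """Shifting (ys, tc) along the mixer relation leaves the simulated
        constant-rate slope unchanged to machine precision."""
        eq_a = EquilibriumParams(ys=0.0093, xt=0.11, K=0.049)
        tc_a, tc_b, tr = 0.3, 0.45, 2.35
        ys_b = ys_shift_mixer(eq_a.ys, tc_a, tc_b, tr)
        eq_b = EquilibriumParams(ys=ys_b, xt=0.11, K=0.049)
        p_a = ModelParams(eq=eq_a, xu=0.345, tc=tc_a, tr=tr, gamma=1.456)
        p_b = ModelParams(eq=eq_b, xu=0.345, tc=tc_b, tr=tr, gamma=1.456)
        slope_a = constant_rate_period(p_a).slope_e
        slope_b = constant_rate_period(p_b).slope_e
        assert slope_b == pytest.approx(slope_a, rel=1e-10)


class TestTailCompensation:
    def test_identity_and_worked_ratio(self):
        assert tc_shift_for_K(0.45, 0.049, 0.049, 2.35) == pytest.approx(0.45, rel=1e-15)
        # tca/tr = 1, Kb/Ka = 2 -> tcb/tr = 1*2 + 2 - 1 = 3
        assert tc_shift_for_K(2.35, 0.01, 0.02, 2.35) == pytest.approx(3 * 2.35, rel=1e-12)

    def test_preserves_dominant_time_constant(self):
        """The compensating shift keeps T1 invariant (exactly, by the
        algebra of T1 = tr*(1+gamma*K+tc/tr)/(gamma*K))."""
        eq_a = EquilibriumParams(ys=0.0093, xt=0.11, K=0.02)
        tc_b = tc_shift_for_K(0.3, 0.02, 0.05, 2.35)
        eq_b = EquilibriumParams(ys=0.0093, xt=0.11, K=0.05)
        T1_a = dominant_time_constant(ModelParams(eq=eq_a, xu=0.345, tc=0.3, tr=2.35, gamma=1.456))
        T1_b = dominant_time_constant(ModelParams(eq=eq_b, xu=0.345, tc=tc_b, tr=2.35, gamma=1.456))
        assert T1_b == pytest.approx(T1_a, rel=1e-12)

    def test_infeasible_shift_reported(self):
        with pytest.raises(ValueError, match="infeasible"):
            tc_shift_for_K(0.05, 0.10, 0.01, 2.35)


class TestBicComparison:
    def test_curve_continuity_and_asymptote(self):
        bp = BicParams(xu=0.345, ys=0.0093, tf=0.3, ti=40.0, q1=26.0, e1=0.22)
        e_at_q1 = bic_curve(bp, tr=2.35, qprime=0.28, q=np.array([26.0]))[0]
        just_after = bic_curve(bp, tr=2.35, qprime=0.28, q=np.array([26.0 + 1e-9]))[0]
        assert just_after == pytest.approx(bp.e1, rel=1e-8)
        far = bic_curve(bp, tr=2.35, qprime=0.28, q=np.array([1e6]))[0]
        assert far == pytest.approx(0.345, rel=1e-12)

    def test_midpoint_value_independent_arithmetic(self):
        bp = BicParams(xu=0.3, ys=0.01, tf=0.5, ti=30.0, q1=20.0, e1=0.18)
        q_mid = 35.0
        e = bic_curve(bp, tr=2.0, qprime=0.25, q=np.array([q_mid]))[0]
        expected = 0.3 - (0.3 - 0.18) * math.exp(-(q_mid - 20.0) / (0.25 * 30.0))
        assert e == pytest.approx(expected, rel=1e-14)

    def test_equivalent_ti_worked_value(self):
        # (1 + gamma*K + tc/tr)/(K*q')
        ti = bic_equivalent_ti(K=0.049, gamma=1.456, tc=0.30, tr=2.35, qprime=0.496)
        assert ti == pytest.approx(49.33, rel=1e-3)

    def test_equivalent_ti_leading_term(self):
        ti = bic_equivalent_ti(K=0.03, gamma=1e-6, tc=1e-9, tr=2.35, qprime=0.4)
        assert ti == pytest.approx(1 / (0.03 * 0.4), rel=1e-5)

    def test_bic_and_desorption_tails_coincide(self, worked_params):
        """With ti from the equivalence relation (and tf = tc), the BIC
        curve and the approximate desorption curve are the same function of
        q — a single run cannot separate the two mechanisms."""
        p = worked_params
        q = np.linspace(0.1, 80.0, 400)
        e_model, q1, e1 = approx_lumped_curve(p, q)
        ti = bic_equivalent_ti(p.eq.K, p.gamma, p.tc, p.tr, p.qprime)
        bp = BicParams(xu=p.xu, ys=p.eq.ys, tf=p.tc, ti=ti, q1=q1, e1=e1)
        e_bic = bic_curve(bp, p.tr, p.qprime, q)
        assert np.max(np.abs(e_bic - e_model)) < 1e-12

    def test_approximation_close_to_exact_when_washing_short(self, worked_params):
        """The two-period approximation drops the washing period; when that
        period is short the sup-norm gap to the exact solution stays below
        5% of the accessible content, and the linear section is exact."""
        p = worked_params
        q = np.linspace(0.05, 200.0, 800)
        e_approx, q1, _ = approx_lumped_curve(p, q)
        e_exact = yield_at(p, q / p.qprime)
        assert np.max(np.abs(e_approx - e_exact)) < 0.05 * p.xu
        lin = q < q1 * 0.999
        assert np.max(np.abs(e_approx[lin] - e_exact[lin])) < 1e-12


class TestMaterialBookkeeping:
    def test_unextractable_fraction_worked_number(self):
        """407 g/kg total oil vs 350 g/kg asymptotic yield: about 14% of
        the oil sits in cells the pretreatment never opened."""
        assert inaccessible_fraction(407.0, 350.0) == pytest.approx(14.0, abs=0.01)

    def test_cell_opening_balance(self):
        """27% open after freeze-drying alone, 70% after crushing: crushing
        opened 43% and 30% stayed intact."""
        split = cell_opening_balance(27.0, 70.0)
        assert split["opened_by_treatment_pct"] == pytest.approx(43.0)
        assert split["intact_pct"] == pytest.approx(30.0)

    def test_invalid_bookkeeping_rejected(self):
        with pytest.raises(ValueError):
            inaccessible_fraction(300.0, 350.0)
        with pytest.raises(ValueError):
            cell_opening_balance(80.0, 70.0)
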