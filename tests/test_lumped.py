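import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfekin import (
    EquilibriumParams,
    ModelParams,
    constant_rate_period,
    desorption_eigen,
    desorption_period,
    dominant_time_constant,
    period_boundaries,
    simulate_lumped,
    washing_period,
    yield_at,
)


class TestConstantRatePeriod:
    def test_worked_break_point(self, worked_params):
        """Hand-checked: t1 = (xu-xt)(tr+tc)/(gamma*ys) - tr and the
        quasi-steady fluid concentration ys*tr/(tr+tc)."""
        cr = constant_rate_period(worked_params)
        assert cr.t1 == pytest.approx(43.640635708, rel=1e-9)
        assert cr.y1 == pytest.approx(0.0093 * 2.35 / 2.65, rel=1e-12)
        assert cr.e1 == pytest.approx(0.345 - 0.11 - 1.456 * cr.y1, rel=1e-12)

    def test_small_holdup_limit(self, nanno_eq):
        """With vanishing solvent holdup the whole free-solute inventory is
        recovered in period 1: e1 -> xu - xt."""
        p = ModelParams(eq=nanno_eq, xu=0.345, tc=0.3, tr=2.35, gamma=1e-7)
        assert constant_rate_period(p).e1 == pytest.approx(0.345 - 0.11, rel=1e-5)

    def test_no_resistance_limit_slope(self, nanno_eq):
        """tc -> 0 removes the transfer resistance; the yield slope tends to
        q'*ys (saturated effluent)."""
        p = ModelParams(eq=nanno_eq, xu=0.345, tc=1e-9, tr=2.35, gamma=1.456)
        assert constant_rate_period(p).slope_e == pytest.approx(p.qprime * 0.0093, rel=1e-8)

    def test_degenerate_when_x0_barely_above_xt(self, nanno_eq):
        p = ModelParams(eq=nanno_eq, xu=0.112, tc=0.3, tr=2.35, gamma=1.456)
        cr = constant_rate_period(p)
        assert cr.t1 == 0.0 and cr.e1 == 0.0


class TestWashingPeriod:
    def test_worked_duration(self, worked_params):
        pb = period_boundaries(worked_params)
        # tr * ln(y1/(K*xt)) with y1 = 0.0082472, K*xt = 0.00539
        assert pb.t2 - pb.t1 == pytest.approx(0.99951305, rel=1e-7)
        assert pb.y2 == pytest.approx(0.049 * 0.11, rel=1e-12)
        assert pb.e2 == pytest.approx(pb.e1 + 1.456 * (pb.y1 - pb.y2), rel=1e-12)

    def test_skipped_when_y1_at_isotherm(self, nanno_eq):
        w = washing_period(
            ModelParams(eq=nanno_eq, xu=0.345, tc=0.3, tr=2.35, gamma=1.456),
            t1=10.0, y1=0.049 * 0.11, e1=0.2, x1=0.11,
        )
        assert w.t2 == 10.0 and w.e2 == 0.2

    def test_irreversible_binding_washes_forever(self, worked_params):
        """K = 0: washing never ends and the extraction terminates at
        e1 + gamma*y1, leaving the adsorbed residue unextracted."""
        eq0 = EquilibriumParams(ys=0.0093, xt=0.11, K=0.0)
        p = ModelParams(eq=eq0, xu=0.345, tc=0.3, tr=2.35, gamma=1.456)
        pb = period_boundaries(p)
        assert math.isinf(pb.t2)
        e_late = yield_at(p, 1e6)
        assert e_late == pytest.approx(pb.e1 + p.gamma * pb.y1, rel=1e-9)
        assert e_late < p.xu  # the bound fraction xt is never recovered


class TestDesorptionPeriod:
    def test_initial_condition_recovery(self, worked_params):
        pb = period_boundaries(worked_params)
        x, y, e = desorption_period(pb.x2, pb.y2, pb.t2, worked_params, pb.t2, e2=pb.e2)
        assert x == pytest.approx(pb.x2, rel=1e-12)
        assert y == pytest.approx(pb.y2, rel=1e-12)
        assert e == pytest.approx(pb.e2, rel=1e-12)

    def test_total_washout_asymptote(self, worked_params):
        pb = period_boundaries(worked_params)
        x, y, e = desorption_period(pb.x2, pb.y2, pb.t2, worked_params, pb.t2 + 1e6, e2=pb.e2)
        assert x == pytest.approx(0.0, abs=1e-15)
        assert y == pytest.approx(0.0, abs=1e-15)
        assert e == pytest.approx(pb.e2 + pb.x2 + worked_params.gamma * pb.y2, rel=1e-12)

    def test_midcourse_against_independent_euler_oracle(self, worked_params):
        """The closed-form state one dominant time constant into desorption
        matches a fixed-step explicit-Euler integration of the raw ODE pair
        (an oracle sharing no code with the solution)."""
        p = worked_params
        K, g, tr, tc = p.eq.K, p.gamma, p.tr, p.tc
        x2, y2 = 0.11, K * 0.11
        T1 = dominant_time_constant(p)

        dt = 1e-5
        x, y = x2, y2
        for _ in range(int(round(T1 / dt))):
            flux = (K * x - y) / tc
            y, x = y + dt * (-y / tr + flux), x - dt * g * flux

        xa, ya, _ = desorption_period(x2, y2, 0.0, p, T1)
        assert xa == pytest.approx(x, rel=1e-6)
        assert ya == pytest.approx(y, rel=1e-6)

    def test_eigenstructure(self, worked_params):
        eig = desorption_eigen(worked_params)
        S_expect = 1 / 2.35 + (1 + 1.456 * 0.049) / 0.30
        assert eig.S == pytest.approx(S_expect, rel=1e-12)
        assert eig.p2 <= eig.p1 <= 0.0
        assert eig.A(0.0) == 0.0
        assert eig.B(0.0) == pytest.approx(eig.R, rel=1e-12)

    def test_before_start_rejected(self, worked_params):
        with pytest.raises(ValueError, match="before"):
            desorption_period(0.11, 0.005, 10.0, worked_params, 9.0)


class TestDominantTimeConstant:
    def test_worked_value(self, worked_params):
        # tr*(1 + gamma*K + tc/tr)/(gamma*K)
        assert dominant_time_constant(worked_params) == pytest.approx(39.494, rel=1e-4)

    def test_approximates_slow_eigenvalue(self, worked_params):
        eig = desorption_eigen(worked_params)
        assert abs(eig.p2 / eig.p1) > 10  # well-separated time scales
        assert dominant_time_constant(worked_params) == pytest.approx(-1 / eig.p1, rel=0.2)

    def test_weak_binding_leading_term(self, nanno_eq):
        eq = EquilibriumParams(ys=0.0093, xt=0.11, K=1e-4)
        p = ModelParams(eq=eq, xu=0.345, tc=1e-4, tr=2.35, gamma=1.456)
        assert dominant_time_constant(p) == pytest.approx(
            p.tr / (p.gamma * eq.K), rel=1e-3
        )

    def test_monotone_sublinear_in_K(self, nanno_eq):
        def T1_of(K):
            eq = EquilibriumParams(ys=0.0093, xt=0.11, K=K)
            return dominant_time_constant(
                ModelParams(eq=eq, xu=0.345, tc=0.3, tr=2.35, gamma=1.456)
            )

        assert T1_of(0.02) / 2 < T1_of(0.04) < T1_of(0.02)

    def test_unextractable_when_K_zero(self):
        eq = EquilibriumParams(ys=0.0093, xt=0.11, K=0.0)
        p = ModelParams(eq=eq, xu=0.345, tc=0.3, tr=2.35, gamma=1.456)
        assert math.isinf(dominant_time_constant(p))


class TestSimulateLumped:
    def test_asymptote_reaches_accessible_content(self, nanno_params):
        df = simulate_lumped(nanno_params, np.array([0.0, 1e5]))
        assert df.e_kgkg.iloc[-1] == pytest.approx(0.345, abs=1e-6)

    def test_empty_system_yields_nothing(self, nanno_eq):
        p = ModelParams(eq=nanno_eq, xu=0.0, tc=0.3, tr=2.35, gamma=1.456)
        df = simulate_lumped(p, np.linspace(0, 50, 100))
        assert np.all(df.e_kgkg == 0.0)

    def test_dispatch_washing_first(self, nanno_eq):
        """Starting exactly at the capacity with supersaturated fluid skips
        dissolution: washing from t = 0, then desorption."""
        p = ModelParams(eq=nanno_eq, xu=0.345, tc=0.3, tr=2.35, gamma=1.456,
                        y0=0.008, x0=0.11)
        pb = period_boundaries(p)
        assert not pb.has_constant_rate and pb.has_washing
        assert pb.t1 == 0.0 and pb.y1 == 0.008 and pb.e1 == 0.0

    def test_dispatch_desorption_only(self, nanno_eq):
        p = ModelParams(eq=nanno_eq, xu=0.345, tc=0.3, tr=2.35, gamma=1.456,
                        y0=0.002, x0=0.05)
        pb = period_boundaries(p)
        assert not pb.has_constant_rate and not pb.has_washing
        assert pb.t2 == 0.0 and pb.x2 == 0.05 and pb.y2 == 0.002
        df = simulate_lumped(p, np.array([0.0, 1e5]))
        assert df.e_kgkg.iloc[-1] == pytest.approx(0.05 + 1.456 * 0.002, rel=1e-9)

    def test_continuity_at_period_boundaries(self, worked_params):
        pb = period_boundaries(worked_params)
        for t_star in (pb.t1, pb.t2):
            t = np.array([t_star - 1e-9, t_star, t_star + 1e-9])
            df = simulate_lumped(worked_params, t)
            for col in ("x_kgkg", "y_kgkg", "e_kgkg"):
                assert np.ptp(df[col].to_numpy()) < 1e-9

    def test_supersaturated_initial_fluid_rejected(self, nanno_eq):
        with pytest.raises(ValueError, match="y0"):
            ModelParams(eq=nanno_eq, xu=0.345, tc=0.3, tr=2.35, gamma=1.456, y0=0.02)

    def test_exact_start_transient(self, nanno_eq):
        """With the exact initial transient the fluid starts at y0 = 0 and
        relaxes to the quasi-steady level within a few tc*tr/(tc+tr)."""
        p = ModelParams(eq=nanno_eq, xu=0.345, tc=0.3, tr=2.35, gamma=1.456)
        df = simulate_lumped(p, np.linspace(0.0, 5.0, 200), exact_start=True)
        yq = 0.0093 * 2.35 / 2.65
        assert df.y_kgkg.iloc[0] == 0.0
        assert df.y_kgkg.iloc[-1] == pytest.approx(yq, rel=1e-6)
        cons = df.x_kgkg + p.gamma * df.y_kgkg + df.e_kgkg
        assert np.ptp(cons.to_numpy()) < 1e-12


def _param_strategy():
    return st.builds(
        lambda ys, xt, kf, xu, tc, tr, gamma: ModelParams(
            eq=EquilibriumParams(ys=ys, xt=xt, K=kf * ys / xt),
            xu=xu, tc=tc, tr=tr, gamma=gamma,
        ),
        ys=st.floats(1e-4, 0.05),
        xt=st.floats(1e-3, 0.3),
        kf=st.floats(0.0, 0.99),
        xu=st.floats(1e-3, 0.5),
        tc=st.floats(0.01, 5.0),
        tr=st.floats(0.1, 10.0),
        gamma=st.floats(0.05, 3.0),
    )


@given(p=_param_strategy())
@settings(max_examples=150, deadline=None)
def test_conservation_monotonicity_and_bounds(p):
    """Across the admissible parameter space (all dispatch branches):
    x + gamma*y + e stays at its initial value to 1e-10, the yield never
    decreases, the solid concentration never increases, and the fluid stays
    within [0, ys]."""
    pb = period_boundaries(p)
    horizon = pb.t2 + 3 * p.tr if math.isfinite(pb.t2) else pb.t1 + 10 * p.tr
    t = np.linspace(0.0, max(horizon, 1.0), 400)
    df = simulate_lumped(p, t)
    total = pb.x_start + p.gamma * pb.y_start
    cons = df.x_kgkg + p.gamma * df.y_kgkg + df.e_kgkg
    assert np.max(np.abs(cons - total)) < 1e-10
    assert np.all(np.diff(df.e_kgkg) >= -1e-12)
    assert np.all(np.diff(df.x_kgkg) <= 1e-12)
    assert np.all(df.y_kgkg >= -1e-15)
    assert np.all(df.y_kgkg <= p.eq.ys * (1 + 1e-9))


@given(p=_param_strategy())
@settings(max_examples=80, deadline=None)
def test_desorption_eigenvalues_always_real(p):
    """S^2 - 4*gamma*K/(tr*tc) equals a sum of squares, so the desorption
    eigenvalues are real and non-positive for every admissible parameter
    set."""
    eig = desorption_eigen(p)
    gK = p.gamma * p.eq.K
    identity = (1 / p.tr + (1 - gK) / p.tc) ** 2 + 4 * gK / p.tc**2
    assert eig.R**2 == pytest.approx(identity, rel=1e-9, abs=1e-12)
    assert eig.p2 <= eig.p1 <= 1e-15
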