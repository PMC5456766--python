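"""Exact three-period solution of the ideal-mixer (lumped-parameter) model.

For a short extraction bed the packed column behaves as a single ideal
mixer.  With the discontinuous equilibrium law of :mod:`sfekin.equilibrium`
the mass balances

    dy/dt = -y/tr + (y+ - y)/tc
    dx/dt = -gamma * (y+ - y)/tc
    e(t)  = q' * integral_0^t y dt,          q' = gamma/tr

admit a closed-form solution consisting of up to three sequential periods:

1. *Constant-rate period* (``x > xt``): free solute dissolves, the fluid
   concentration sits at the quasi-steady value ``ys*tr/(tr+tc)`` and the
   yield grows linearly.
2. *Washing period* (``x = xt``, ``y > K*xt``): no mass transfer; the
   solute already dissolved is washed out exponentially with time constant
   ``tr``.
3. *Desorption period* (``x < xt``): the linear isotherm couples x and y
   into a 2x2 linear ODE system whose eigenvalues are both real and
   negative; the extract tails off bi-exponentially.

Any of the first two periods may be absent depending on the initial state.
The solution conserves mass exactly: ``x + gamma*y + e`` is constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .equilibrium import EquilibriumParams

__all__ = [
    "ModelParams",
    "PeriodBoundaries",
    "DesorptionEigen",
    "ConstantRatePeriod",
    "WashingPeriod",
    "constant_rate_period",
    "washing_period",
    "desorption_eigen",
    "desorption_period",
    "dominant_time_constant",
    "period_boundaries",
    "yield_at",
    "simulate_lumped",
    "default_horizon",
]

PERIOD_LABELS = {1: "constant-rate", 2: "washing", 3: "desorption"}


@dataclass
class ModelParams:
    """Full parameter set of one simulated extraction.

    Parameters
    ----------
    eq : EquilibriumParams
        Phase-equilibrium law (ys, xt, K).
    xu : float
        Accessible solute content of the feed, kg/kg (solute in cells opened
        by the pretreatment; solute in intact cells is invisible to CO2).
    tc : float
        Characteristic mass-transfer time, min (film + internal).
    tr : float
        Residence time of CO2 in the bed voids, min.
    gamma : float
        CO2-to-feed mass ratio in the voids, kg/kg.
    y0 : float
        Initial fluid-phase concentration, kg/kg (default 0: fresh CO2).
    x0 : float, optional
        Initial solid-phase concentration; defaults to ``xu - gamma*y0`` so
        that the total solute inventory equals ``xu``.
    """

    eq: EquilibriumParams
    xu: float
    tc: float
    tr: float
    gamma: float
    y0: float = 0.0
    x0: float | None = None

    def __post_init__(self) -> None:
        if self.x0 is None:
            self.x0 = self.xu - self.gamma * self.y0
        self.validate()

    @property
    def qprime(self) -> float:
        """Specific solvent flow rate q' = gamma/tr, 1/min."""
        return self.gamma / self.tr

    @property
    def total(self) -> float:
        """Total solute inventory x0 + gamma*y0, conserved by the model."""
        return self.x0 + self.gamma * self.y0

    def validate(self) -> None:
        eq_problems = self.eq.violations()
        if eq_problems:
            raise ValueError("invalid equilibrium parameters: " + "; ".join(eq_problems))
        if self.xu < 0:
            raise ValueError("xu must be non-negative")
        for name in ("tc", "tr", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.x0 < 0:
            raise ValueError("x0 must be non-negative")
        # admissible initial fluid concentration: below saturation while free
        # solute is present, below the isotherm ceiling K*xt otherwise
        if self.x0 >= self.eq.xt:
            if not (0.0 <= self.y0 <= self.eq.ys + 1e-15):
                raise ValueError("require 0 <= y0 <= ys when x0 >= xt")
        else:
            if not (0.0 <= self.y0 <= self.eq.K * self.eq.xt + 1e-15):
                raise ValueError("require 0 <= y0 <= K*xt when x0 < xt")
        if self.x0 + self.gamma * self.y0 > self.xu + 1e-12:
            raise ValueError("x0 + gamma*y0 exceeds the accessible content xu")


@dataclass(frozen=True)
class PeriodBoundaries:
    """Transition points between the (up to) three extraction periods.

    ``t1`` ends the constant-rate period, ``t2`` starts desorption
    (``t2 = inf`` when ``K = 0``: the washing tail is never left).
    ``x_start``/``y_start`` are the effective initial state actually used
    by the solution (the quasi-steady start resets ``y`` to
    ``ys*tr/(tr+tc)``).
    """

    t1: float
    y1: float
    e1: float
    x1: float
    t2: float
    y2: float
    x2: float
    e2: float
    has_constant_rate: bool
    has_washing: bool
    x_start: float
    y_start: float
    exact_start: bool = False


@dataclass(frozen=True)
class ConstantRatePeriod:
    """Closed forms of the free-solute dissolution period."""

    y_const: float  #: quasi-steady fluid concentration ys*tr/(tr+tc)
    slope_e: float  #: d(e)/dt = q'*ys/(1+tc/tr)
    t1: float
    y1: float
    e1: float
    x1: float


@dataclass(frozen=True)
class WashingPeriod:
    t2: float
    y2: float
    e2: float
    x2: float


@dataclass(frozen=True)
class DesorptionEigen:
    """Eigen-structure of the desorption-period 2x2 linear system.

    ``p1 >= p2`` are the (real, non-positive) eigenvalues of

        d/dt [y, x] = [[-(1/tr + 1/tc), K/tc], [gamma/tc, -gamma*K/tc]] [y, x]

    with ``S = -(p1+p2) = 1/tr + (1+gamma*K)/tc`` and ``R = p1 - p2``.
    """

    S: float
    R: float
    p1: float
    p2: float

    def A(self, tau):
        """exp(p1*tau) - exp(p2*tau); A(0) = 0."""
        tau = np.asarray(tau, dtype=float)
        return np.exp(self.p1 * tau) - np.exp(self.p2 * tau)

    def B(self, tau):
        """p1*exp(p1*tau) - p2*exp(p2*tau); B(0) = R."""
        tau = np.asarray(tau, dtype=float)
        return self.p1 * np.exp(self.p1 * tau) - self.p2 * np.exp(self.p2 * tau)


def _y_qss(p: ModelParams) -> float:
    return p.eq.ys * p.tr / (p.tr + p.tc)


def constant_rate_period(p: ModelParams) -> ConstantRatePeriod:
    """Closed forms of the constant-rate (free-solute) period.

    The quasi-steady fluid concentration is ``ys*tr/(tr+tc)`` and the yield
    grows with slope ``q'*ys/(1+tc/tr)`` until the solid concentration
    reaches the adsorption capacity at

        t1 = (xu - xt)*(tr + tc)/(gamma*ys) - tr

    A computed ``t1 < 0`` (initial solid barely above ``xt``) degenerates to
    a zero-length period.
    """
    if p.x0 < p.eq.xt:
        raise ValueError("constant-rate period requires x0 >= xt")
    ys, xt = p.eq.ys, p.eq.xt
    yq = _y_qss(p)
    slope = p.qprime * ys / (1.0 + p.tc / p.tr)
    t1 = (p.xu - xt) * (p.tr + p.tc) / (p.gamma * ys) - p.tr
    if t1 <= 0.0:
        # zero-length period: the solvent holdup swallows the free-solute
        # excess before the quasi-steady state could establish
        return ConstantRatePeriod(yq, slope, 0.0, yq, 0.0, xt)
    e1 = p.xu - xt - p.gamma * yq
    return ConstantRatePeriod(yq, slope, t1, yq, e1, xt)


def washing_period(p: ModelParams, t1: float, y1: float, e1: float, x1: float) -> WashingPeriod:
    """End point of the exponential washing period.

    Washing holds the solid at ``x1`` while the dissolved solute leaves with
    time constant ``tr``; it ends when the fluid concentration has fallen to
    the isotherm value ``K*xt``.  If ``y1 <= K*xt`` the period is skipped.
    For ``K = 0`` washing never ends (``t2 = inf``) and the extraction
    terminates at ``e1 + gamma*y1``, leaving the adsorbed residue behind.
    """
    K, xt = p.eq.K, p.eq.xt
    if K <= 0.0:
        return WashingPeriod(math.inf, 0.0, e1 + p.gamma * y1, x1)
    if y1 <= K * xt:
        return WashingPeriod(t1, y1, e1, x1)
    t2 = t1 + p.tr * math.log(y1 / (K * xt))
    y2 = K * xt
    e2 = e1 + p.gamma * (y1 - y2)
    return WashingPeriod(t2, y2, e2, x1)


def desorption_eigen(p: ModelParams) -> DesorptionEigen:
    gK = p.gamma * p.eq.K
    S = 1.0 / p.tr + (1.0 + gK) / p.tc
    disc = S * S - 4.0 * gK / (p.tr * p.tc)
    # algebraically disc = (1/tr + (1-gK)/tc)^2 + 4*gK/tc^2 >= 0; clip the
    # roundoff tail so sqrt never sees a tiny negative number
    R = math.sqrt(max(disc, 0.0))
    p1 = 0.5 * (-S + R)
    p2 = 0.5 * (-S - R)
    return DesorptionEigen(S=S, R=R, p1=p1, p2=p2)


def desorption_period(x2: float, y2: float, t2: float, p: ModelParams, t, e2: float = 0.0):
    """State during the desorption period, continuous at ``t = t2``.

    Solves d/dt y = -y/tr + (K*x - y)/tc, d/dt x = -gamma*(K*x - y)/tc for
    arbitrary initial concentrations ``(x2, y2)`` via the spectral
    decomposition of the system matrix:

        y = [K*(x2 + gamma*y2)/tc * A + y2 * B] / R
        x = [(x2/tr + (x2 + gamma*y2)/tc) * A + x2 * B] / R

    with ``A = exp(p1 (t-t2)) - exp(p2 (t-t2))`` and
    ``B = p1 exp(p1 (t-t2)) - p2 exp(p2 (t-t2))``.  The yield follows from
    conservation; as ``t -> inf`` everything washes out and
    ``e -> e2 + x2 + gamma*y2``.

    Returns ``(x, y, e)`` as floats or arrays matching ``t``.
    """
    K = p.eq.K
    tau = np.asarray(t, dtype=float) - t2
    if np.any(tau < -1e-12):
        raise ValueError("desorption_period evaluated before its start time t2")
    tau = np.maximum(tau, 0.0)
    if K <= 0.0:
        # zero isotherm: admissible initial fluid concentration is y2 = 0,
        # the system is inert (no driving force) and nothing more is extracted
        shape = tau.shape
        x = np.full(shape, x2)
        y = np.full(shape, y2)
        e = np.full(shape, e2)
    else:
        eig = desorption_eigen(p)
        A = eig.A(tau)
        B = eig.B(tau)
        hold = x2 + p.gamma * y2
        y = (K * hold / p.tc * A + y2 * B) / eig.R
        x = ((x2 / p.tr + hold / p.tc) * A + x2 * B) / eig.R
        e = e2 + hold - x - p.gamma * y
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(x), float(y), float(e)
    return x, y, e


def dominant_time_constant(p: ModelParams) -> float:
    """Approximate dominant time constant T1 of the desorption tail, min.

    ``T1 = tr*(1 + gamma*K + tc/tr)/(gamma*K)``; it approximates ``-1/p1``
    when the two eigenvalues are well separated.  Infinite for ``K = 0``
    (the adsorbed residue is never extracted).
    """
    gK = p.gamma * p.eq.K
    if gK <= 0.0:
        return math.inf
    return p.tr * (1.0 + gK + p.tc / p.tr) / gK


def period_boundaries(p: ModelParams, exact_start: bool = False) -> PeriodBoundaries:
    """Dispatch the initial state to the applicable periods.

    * ``x0 > xt``: all three periods (the constant-rate period may
      degenerate to zero length);
    * ``x0 = xt`` with ``K*xt < y0 <= ys``: washing then desorption;
    * ``x0 < xt`` (or ``x0 = xt`` with ``y0 <= K*xt``): desorption only.

    With the default quasi-steady start the constant-rate period uses the
    simplified constant fluid concentration; ``exact_start=True`` keeps the
    exponential transient from the true ``y0`` (the effect of initial
    conditions disappears within a few ``tc*tr/(tc+tr)``).
    """
    xt, K = p.eq.xt, p.eq.K
    if p.x0 > xt:
        # the quasi-steady start is only meaningful while the implied
        # initial solid xu - gamma*y_qss stays above xt (t1 > 0); otherwise
        # the holdup swallows the free-solute excess and the exact transient
        # is the physical description
        use_exact = exact_start or constant_rate_period(p).t1 <= 0.0
        if use_exact:
            t1, y1, e1, x1 = _exact_start_boundary(p)
            x_start, y_start = p.x0, p.y0
            exact_start = True
        else:
            cr = constant_rate_period(p)
            t1, y1, e1, x1 = cr.t1, cr.y1, cr.e1, cr.x1
            y_start = cr.y_const
            x_start = p.xu - p.gamma * y_start
        w = washing_period(p, t1, y1, e1, x1)
        return PeriodBoundaries(
            t1=t1, y1=y1, e1=e1, x1=x1,
            t2=w.t2, y2=w.y2, x2=w.x2, e2=w.e2,
            has_constant_rate=True, has_washing=w.t2 > t1,
            x_start=x_start, y_start=y_start, exact_start=exact_start,
        )
    if p.x0 == xt and p.y0 > K * xt:
        w = washing_period(p, 0.0, p.y0, 0.0, xt)
        return PeriodBoundaries(
            t1=0.0, y1=p.y0, e1=0.0, x1=xt,
            t2=w.t2, y2=w.y2, x2=w.x2, e2=w.e2,
            has_constant_rate=False, has_washing=True,
            x_start=p.x0, y_start=p.y0, exact_start=exact_start,
        )
    return PeriodBoundaries(
        t1=0.0, y1=p.y0, e1=0.0, x1=p.x0,
        t2=0.0, y2=p.y0, x2=p.x0, e2=0.0,
        has_constant_rate=False, has_washing=False,
        x_start=p.x0, y_start=p.y0, exact_start=exact_start,
    )


def _exact_start_state(p: ModelParams, t):
    """(x, y, e) during the constant-rate period with the exact transient."""
    t = np.asarray(t, dtype=float)
    ys = p.eq.ys
    yq = _y_qss(p)
    tau = p.tc * p.tr / (p.tc + p.tr)  # transient time constant
    y = yq + (p.y0 - yq) * np.exp(-t / tau)
    Y = yq * t + (p.y0 - yq) * tau * (1.0 - np.exp(-t / tau))  # integral of y
    x = p.x0 - (p.gamma / p.tc) * (ys * t - Y)
    e = p.qprime * Y
    return x, y, e


def _exact_start_boundary(p: ModelParams):
    """Numerically locate t1 where x(t1) = xt under the exact transient."""
    xt = p.eq.xt

    def f(t):
        return _exact_start_state(p, t)[0] - xt

    if f(0.0) <= 0.0:
        return 0.0, p.y0, 0.0, p.x0
    # the asymptotic decline is linear with slope -gamma*ys/(tr+tc)
    t_hi = (p.x0 - xt) * (p.tr + p.tc) / (p.gamma * p.eq.ys) + 10.0 * (p.tc + p.tr)
    while f(t_hi) > 0.0:  # pragma: no cover - generous initial bracket
        t_hi *= 2.0
    t1 = brentq(f, 0.0, t_hi, xtol=1e-14, rtol=1e-15)
    _, y1, e1 = (v.item() if hasattr(v, "item") else v for v in _exact_start_state(p, t1))
    return t1, float(y1), float(e1), xt


def _states(p: ModelParams, pb: PeriodBoundaries, t: np.ndarray):
    """Vectorized piecewise evaluation of (x, y, e, period-code) at times t."""
    t = np.asarray(t, dtype=float)
    x = np.empty_like(t)
    y = np.empty_like(t)
    e = np.empty_like(t)
    code = np.empty(t.shape, dtype=int)

    m1 = t <= pb.t1 if pb.has_constant_rate else np.zeros(t.shape, dtype=bool)
    m2 = (~m1) & (t <= pb.t2)
    m3 = ~(m1 | m2)

    if m1.any():
        if pb.exact_start:
            x[m1], y[m1], e[m1] = _exact_start_state(p, t[m1])
        else:
            yq = pb.y_start
            y[m1] = yq
            e[m1] = p.qprime * yq * t[m1]
            x[m1] = pb.x_start - p.gamma * p.eq.ys * t[m1] / (p.tr + p.tc)
        code[m1] = 1
    if m2.any():
        decay = np.exp(-(t[m2] - pb.t1) / p.tr)
        y[m2] = pb.y1 * decay
        x[m2] = pb.x1
        e[m2] = pb.e1 + p.gamma * pb.y1 * (1.0 - decay)
        code[m2] = 2
    if m3.any():
        x[m3], y[m3], e[m3] = desorption_period(pb.x2, pb.y2, pb.t2, p, t[m3], e2=pb.e2)
        code[m3] = 3
    return x, y, e, code


def yield_at(p: ModelParams, t, exact_start: bool = False):
    """Cumulative extraction yield e(t), kg extract per kg feed.

    Fast closed-form evaluation at arbitrary times; the workhorse of curve
    fitting.
    """
    pb = period_boundaries(p, exact_start=exact_start)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("times must be non-negative")
    _, _, e, _ = _states(p, pb, t_arr)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(e[0])
    return e


def default_horizon(p: ModelParams, tails: float = 8.0) -> float:
    """A time horizon by which the extractable solute is essentially gone."""
    pb = period_boundaries(p)
    if p.eq.K > 0.0 and math.isfinite(pb.t2):
        return pb.t2 + tails * dominant_time_constant(p)
    return pb.t1 + tails * p.tr


def simulate_lumped(p: ModelParams, t_grid, exact_start: bool = False) -> pd.DataFrame:
    """Simulate the full three-period extraction on a time grid.

    Returns a table with columns ``t_min``, ``q_kgkg`` (solvent-to-feed
    ratio ``q'*t``), ``x_kgkg``, ``y_kgkg``, ``e_kgkg`` and ``period``.
    The trajectory conserves ``x + gamma*y + e`` exactly and the yield is
    continuous and non-decreasing, approaching ``x_start + gamma*y_start``
    (equal to ``xu`` for the default initial state) as ``t -> inf``.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("t_grid must be non-negative and non-decreasing")
    pb = period_boundaries(p, exact_start=exact_start)
    x, y, e, code = _states(p, pb, t)
    return pd.DataFrame(
        {
            "t_min": t,
            "q_kgkg": p.qprime * t,
            "x_kgkg": x,
            "y_kgkg": y,
            "e_kgkg": e,
            "period": [PERIOD_LABELS[c] for c in code],
        }
    )
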