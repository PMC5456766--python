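"""Parameter-interaction relations and the broken-and-intact-cell comparison.

Because the yield curve is shaped jointly by equilibrium, mass transfer and
flow pattern, several parameter combinations produce identical observable
features.  The relations here make those ridges explicit:

* the initial slope fixes only a combination of ``ys`` and ``tc``
  (:func:`ys_shift_plug`, :func:`ys_shift_mixer`);
* the desorption tail fixes only a combination of ``tc`` and ``K`` through
  the dominant time constant (:func:`tc_shift_for_K`).

The module also relates the desorption model to the broken-and-intact-cell
(BIC) description: both predict a linear start and an exponential second
period, but the BIC tail is controlled by extraction *time* via an internal
diffusion constant ``ti`` whereas the desorption tail is controlled by the
solvent-to-feed *ratio*.  On a single run at fixed flow the two are
indistinguishable when ``ti = (1 + gamma*K + tc/tr)/(K*q')``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lumped import ModelParams, constant_rate_period, dominant_time_constant

__all__ = [
    "ys_shift_plug",
    "ys_shift_mixer",
    "tc_shift_for_K",
    "BicParams",
    "bic_curve",
    "approx_lumped_curve",
    "bic_equivalent_ti",
    "inaccessible_fraction",
    "cell_opening_balance",
]


def ys_shift_plug(ys_a: float, tc_a: float, tc_b: float, tr: float) -> float:
    """Solubility compensating a tc change at a fixed plug-flow initial slope.

    ys_b/ys_a = (1 - exp(-tr/tc_a)) / (1 - exp(-tr/tc_b)).  For tr >> tc
    the ratio tends to 1: a saturated outlet determines ys uniquely.
    """
    if min(ys_a, tc_a, tc_b, tr) <= 0:
        raise ValueError("all arguments must be positive")
    return ys_a * (1.0 - math.exp(-tr / tc_a)) / (1.0 - math.exp(-tr / tc_b))


def ys_shift_mixer(ys_a: float, tc_a: float, tc_b: float, tr: float) -> float:
    """Solubility compensating a tc change at a fixed ideal-mixer slope.

    ys_b/ys_a = (tr + tc_b)/(tr + tc_a); the lumped period-1 slope
    q'*ys/(1 + tc/tr) is then unchanged.
    """
    if min(ys_a, tc_a, tc_b, tr) <= 0:
        raise ValueError("all arguments must be positive")
    return ys_a * (tr + tc_b) / (tr + tc_a)


def tc_shift_for_K(tc_a: float, K_a: float, K_b: float, tr: float) -> float:
    """Mass-transfer time compensating a K change at a fixed desorption tail.

    tc_b/tr = (tc_a/tr)*(K_b/K_a) + K_b/K_a - 1 keeps the dominant time
    constant T1 of the desorption tail unchanged (to leading order in
    gamma*K).  Raises if the required tc_b is non-positive (infeasible
    shift).
    """
    if min(tc_a, K_a, K_b, tr) <= 0:
        raise ValueError("all arguments must be positive")
    ratio = K_b / K_a
    tc_b = tr * ((tc_a / tr) * ratio + ratio - 1.0)
    if tc_b <= 0:
        raise ValueError(
            f"infeasible shift: compensating tc_b = {tc_b:g} min is not positive"
        )
    return tc_b


@dataclass(frozen=True)
class BicParams:
    """Parameters of the approximate broken-and-intact-cell curve.

    xu, ys as in :class:`~sfekin.lumped.ModelParams`; tf is the external
    film time (min) governing the linear start, ti the internal-diffusion
    time (min) governing the tail; (q1, e1) is the break point in the
    (solvent-to-feed ratio, yield) plane.
    """

    xu: float
    ys: float
    tf: float
    ti: float
    q1: float
    e1: float

    def __post_init__(self) -> None:
        if min(self.xu, self.ys, self.tf, self.ti, self.q1) <= 0:
            raise ValueError("xu, ys, tf, ti, q1 must be positive")
        if not (0.0 <= self.e1 <= self.xu):
            raise ValueError("require 0 <= e1 <= xu")


def bic_curve(bp: BicParams, tr: float, qprime: float, q) -> np.ndarray:
    """Approximate BIC extraction curve e(q).

    Linear up to the break point, then an exponential approach to ``xu``
    controlled by extraction time through ``ti``:

        e = q*ys/(1 + tf/tr)                      for q <= q1
        e = xu - (xu - e1)*exp(-(q - q1)/(q'*ti)) for q >  q1
    """
    q = np.asarray(q, dtype=float)
    linear = q * bp.ys / (1.0 + bp.tf / tr)
    tail = bp.xu - (bp.xu - bp.e1) * np.exp(-(q - bp.q1) / (qprime * bp.ti))
    return np.where(q <= bp.q1, linear, tail)


def approx_lumped_curve(p: ModelParams, q) -> tuple[np.ndarray, float, float]:
    """Approximate two-period form of the lumped desorption model, e(q).

    Ignores the short washing period: the exponential tail starts straight
    from the break point ``(q1, e1)`` of the constant-rate period with the
    dominant time constant T1,

        e = q*ys/(1 + tc/tr)                        for q <= q1
        e = xu - (xu - e1)*exp(-(q - q1)/(T1*q'))   for q >  q1

    and ``T1*q' = (1 + gamma*K + tc/tr)/K``.  Returns ``(e, q1, e1)``.
    """
    if p.eq.K <= 0:
        raise ValueError("the approximate tail requires K > 0")
    q = np.asarray(q, dtype=float)
    cr = constant_rate_period(p)
    q1 = p.qprime * cr.t1
    e1 = cr.e1
    linear = q * p.eq.ys / (1.0 + p.tc / p.tr)
    scale = dominant_time_constant(p) * p.qprime  # = (1 + gamma*K + tc/tr)/K
    tail = p.xu - (p.xu - e1) * np.exp(-(q - q1) / scale)
    return np.where(q <= q1, linear, tail), q1, e1


def bic_equivalent_ti(K: float, gamma: float, tc: float, tr: float, qprime: float) -> float:
    """Internal-diffusion time making the BIC tail coincide with desorption.

    ti = (1 + gamma*K + tc/tr)/(K*q'); with this value the BIC second
    period and the approximate desorption second period are the same curve,
    so a single run cannot distinguish the two mechanisms.
    """
    if K <= 0 or qprime <= 0:
        raise ValueError("K and qprime must be positive")
    return (1.0 + gamma * K + tc / tr) / (K * qprime)


def inaccessible_fraction(total_content: float, asymptotic_yield: float) -> float:
    """Percentage of solute that extraction cannot reach, in percent.

    Compares the asymptotic extraction yield with the total solute content
    (e.g. from Soxhlet n-hexane extraction, which permeabilizes cell
    walls): the shortfall is attributed to solute locked in intact cells.
    """
    if total_content <= 0:
        raise ValueError("total_content must be positive")
    if not (0.0 <= asymptotic_yield <= total_content):
        raise ValueError("asymptotic_yield must lie in [0, total_content]")
    return (total_content - asymptotic_yield) / total_content * 100.0


def cell_opening_balance(open_untreated: float, open_treated: float) -> dict[str, float]:
    """Bookkeeping of cell-wall opening by successive pretreatments, percent.

    Given the percentage of cells open before an additional treatment
    (e.g. after freeze-drying alone) and after it (e.g. after crushing),
    returns the split into cells opened by each stage and cells still
    intact.
    """
    if not (0.0 <= open_untreated <= open_treated <= 100.0):
        raise ValueError("require 0 <= open_untreated <= open_treated <= 100")
    return {
        "open_before_treatment_pct": open_untreated,
        "opened_by_treatment_pct": open_treated - open_untreated,
        "intact_pct": 100.0 - open_treated,
    }
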