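"""Plug-flow limit of the packed-bed model and regime classification.

With no axial mixing the free-solute period has a closed form: the axial
fluid profile is ``y(z) = ys*(1 - exp(-z*tr/tc))`` and the yield grows
linearly with slope ``q'*ys*(1 - exp(-tr/tc))``.  Once the solid
concentration reaches the adsorption capacity anywhere in the bed the
desorption front moves axially and no closed form exists; that phase is
realized as a large-n mixer cascade (default n = 100) rather than by a
second integrator with identical physics.

Two limiting regimes bracket the general case:

* ``tc/tr < 0.02`` — mass-transfer resistance negligible; the effluent is
  at equilibrium and the yield depends on the solvent-to-feed ratio only
  (``e = K*x0*q`` during desorption).
* ``tc/tr > 2`` — the flow pattern is immaterial; the lumped model applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lumped import ModelParams

__all__ = [
    "PlugFlowProfile",
    "plugflow_free_solute",
    "plugflow_slope",
    "free_solute_horizon",
    "regime_classify",
    "equilibrium_controlled_yield",
    "PLUGFLOW_SURROGATE_N",
]

#: number of mixers used as the plug-flow surrogate in the desorption phase
PLUGFLOW_SURROGATE_N = 100

EQUILIBRIUM_CONTROLLED = "equilibrium-controlled"
MIXING_INSENSITIVE = "mixing-insensitive"
INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class PlugFlowProfile:
    """Axial snapshot of the plug-flow free-solute period at one time."""

    t: float
    z: np.ndarray  #: dimensionless axial coordinate in [0, 1]
    y: np.ndarray  #: fluid concentration profile, kg/kg
    x: np.ndarray  #: solid concentration profile, kg/kg
    e: float  #: cumulative yield at time t, kg/kg
    horizon: float  #: validity limit: first time x(z=0) reaches xt


def plugflow_slope(p: ModelParams) -> float:
    """Initial yield slope de/dt of the plug-flow model, kg/kg per min."""
    return p.qprime * p.eq.ys * (1.0 - math.exp(-p.tr / p.tc))


def free_solute_horizon(p: ModelParams) -> float:
    """Time at which the inlet-end solid concentration reaches xt.

    The inlet end (z = 0) sees the largest driving force and depletes
    first; beyond this time the free-solute closed form no longer holds
    everywhere in the bed.
    """
    return (p.x0 - p.eq.xt) * p.tc / (p.gamma * p.eq.ys)


def plugflow_free_solute(p: ModelParams, t: float, z=None) -> PlugFlowProfile:
    """Closed-form plug-flow state during the free-solute period.

    Parameters
    ----------
    p : ModelParams
        Requires ``x0 >= xt`` (free solute present everywhere initially).
    t : float
        Time, min; must not exceed the validity horizon.
    z : array_like, optional
        Axial grid in [0, 1]; default 101 equidistant points.

    Raises
    ------
    ValueError
        If called beyond the validity horizon or with ``x0 < xt``.
    """
    if p.x0 < p.eq.xt:
        raise ValueError("plug-flow free-solute form requires x0 >= xt")
    horizon = free_solute_horizon(p)
    if t > horizon:
        raise ValueError(
            f"t={t:g} min exceeds the free-solute validity horizon {horizon:g} min"
        )
    if z is None:
        z = np.linspace(0.0, 1.0, 101)
    z = np.asarray(z, dtype=float)
    ys = p.eq.ys
    damp = np.exp(-z * p.tr / p.tc)
    y = ys * (1.0 - damp)
    x = p.x0 - p.gamma * ys * (t / p.tc) * damp
    e = plugflow_slope(p) * t
    return PlugFlowProfile(t=float(t), z=z, y=y, x=x, e=float(e), horizon=horizon)


def regime_classify(tc: float, tr: float) -> str:
    """Classify the extraction regime from the time-constant ratio tc/tr.

    Returns one of ``"equilibrium-controlled"`` (tc/tr < 0.02; use the
    solvent-ratio law ``e = K*x0*q``), ``"mixing-insensitive"``
    (tc/tr > 2; the lumped model suffices) or ``"intermediate"``
    (resolve the flow pattern with the n-mixer cascade).
    """
    if tc <= 0 or tr <= 0:
        raise ValueError("tc and tr must be positive")
    ratio = tc / tr
    if ratio < 0.02:
        return EQUILIBRIUM_CONTROLLED
    if ratio > 2.0:
        return MIXING_INSENSITIVE
    return INTERMEDIATE


def equilibrium_controlled_yield(K: float, x0: float, q) -> np.ndarray:
    """Desorption yield in the equilibrium-controlled limit: e = K*x0*q.

    Valid early in the desorption of an initially sub-capacity bed
    (``x0 < xt``) when the effluent leaves saturated; the linear growth
    flattens as the bed depletes.
    """
    return K * x0 * np.asarray(q, dtype=float)
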