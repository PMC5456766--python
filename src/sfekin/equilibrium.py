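"""Discontinuous solid-fluid phase equilibrium for lipid extraction.

The equilibrium law distinguishes free solute from matrix-bound solute.
While the solid-phase concentration ``x`` exceeds the adsorption capacity
``xt``, free lipid is present and the fluid-phase equilibrium concentration
equals the solubility ``ys``.  Below ``xt`` all remaining solute is adsorbed
on the microalga matrix and equilibrium follows a linear isotherm with
partition coefficient ``K``::

    y+ = ys      for x >= xt
    y+ = K * x   for x <  xt        (with K < ys/xt)

The constraint ``K < ys/xt`` guarantees the isotherm branch lies below the
solubility plateau, so ``y+`` is non-decreasing in ``x``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["EquilibriumParams", "y_plus", "validate"]


@dataclass(frozen=True)
class EquilibriumParams:
    """Parameters of the piecewise solid-fluid equilibrium law.

    Parameters
    ----------
    ys : float
        Solubility of the extract in supercritical CO2, kg per kg CO2.
    xt : float
        Adsorption capacity of the matrix, kg per kg dry feed.  Below this
        solid-phase concentration all remaining solute is matrix-bound.
    K : float
        Partition coefficient of the linear isotherm (fluid concentration
        per solid concentration), kg/kg.  ``K = 0`` models irreversible
        binding: the adsorbed fraction is never extracted.
    """

    ys: float
    xt: float
    K: float

    def violations(self) -> list[str]:
        return validate(self)

    @property
    def is_valid(self) -> bool:
        return not validate(self)

    def require_valid(self) -> "EquilibriumParams":
        problems = validate(self)
        if problems:
            raise ValueError("invalid equilibrium parameters: " + "; ".join(problems))
        return self


def validate(eq: EquilibriumParams) -> list[str]:
    """Report every violated constraint of the equilibrium law.

    Returns an empty list iff the parameter set is valid.  This is a
    reporting operation; it never raises.
    """
    problems: list[str] = []
    for name in ("ys", "xt", "K"):
        v = getattr(eq, name)
        if not math.isfinite(v):
            problems.append(f"{name} is not finite")
    if problems:
        return problems
    if eq.ys <= 0:
        problems.append("ys <= 0")
    if eq.xt < 0:
        problems.append("xt < 0")
    if eq.K < 0:
        problems.append("K < 0")
    # Isotherm must stay below the solubility plateau; vacuous when xt == 0
    # (the partition branch is then never used).
    if eq.xt > 0 and eq.ys > 0 and eq.K >= eq.ys / eq.xt:
        problems.append("K >= ys/xt")
    return problems


def y_plus(x, eq: EquilibriumParams):
    """Equilibrium fluid-phase concentration for solid-phase concentration x.

    The boundary ``x == xt`` evaluates to the free-solute branch (``ys``),
    matching the inequality ``x >= xt`` of the equilibrium law.

    Parameters
    ----------
    x : float or array_like
        Solid-phase concentration, kg/kg feed; must be non-negative.
    eq : EquilibriumParams

    Returns
    -------
    float or ndarray
        ``ys`` where ``x >= xt``, ``K*x`` where ``x < xt``.
    """
    eq.require_valid()
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise ValueError("solid-phase concentration x must be non-negative")
    out = np.where(xa >= eq.xt, eq.ys, eq.K * xa)
    if np.isscalar(x) or xa.ndim == 0:
        return float(out)
    return out
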