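"""Extraction-bed characterization: solvent holdup and flow-derived quantities.

All internal units: mass kg, time min, length m, concentration kg/kg.
Converters (grams, hours) belong at the I/O boundary only.

The bed is characterized by the CO2-to-feed mass ratio in the voids,

    gamma = eps * rho_f / ((1 - eps) * rho_s)      (neat alga bed)
    gamma = rho_f * eps * V / N                     (alga mixed with beads)

the specific flow rate q' = Q'/N (per-minute), and the mean residence time
of CO2 in the voids tr = gamma / q'.  The identity q' * tr = gamma holds
exactly and is what closes the overall mass balance at e(inf) = xu.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BedSpec", "FlowDerived", "gamma_of", "flow_derived", "co2_density"]

#: default void fractions: neat alga bed vs alga mixed with inert glass beads
EPS_DEFAULT_NO_BEADS = 0.35
EPS_DEFAULT_WITH_BEADS = 0.40
#: default particle density of dry microalga, kg/m3
RHO_S_DEFAULT = 950.0


@dataclass
class BedSpec:
    """Geometry, feed and flow data of one extraction run.

    Parameters
    ----------
    N : float
        Feed mass of dry alga, kg.
    Qp : float
        CO2 mass flow rate Q', kg/min.
    rho_f : float
        CO2 density at the run pressure and temperature, kg/m3.  A required
        user input; :func:`co2_density` is an optional convenience hook.
    eps : float, optional
        Bed void fraction.  Defaults to 0.40 with beads, 0.35 without.
    rho_s : float
        Particle density of the alga, kg/m3 (default 950).
    V : float, optional
        Extraction-bed volume, m3.  Required when ``with_beads``.
    with_beads : bool
        Whether the alga is mixed with inert glass beads.
    dp : float, optional
        Particle diameter, m (used by mass-transfer estimates).
    SE : float, optional
        Extractor cross-section area, m2 (used by mass-transfer estimates).
    """

    N: float
    Qp: float
    rho_f: float
    eps: float | None = None
    rho_s: float = RHO_S_DEFAULT
    V: float | None = None
    with_beads: bool = False
    dp: float | None = None
    SE: float | None = None

    def __post_init__(self) -> None:
        if self.eps is None:
            self.eps = EPS_DEFAULT_WITH_BEADS if self.with_beads else EPS_DEFAULT_NO_BEADS
        if not (0.0 < self.eps < 1.0):
            raise ValueError(f"void fraction eps={self.eps} outside (0, 1)")
        for name in ("N", "Qp", "rho_s", "rho_f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FlowDerived:
    """Solvent-to-feed quantities derived from a :class:`BedSpec`."""

    gamma: float  #: CO2 mass in bed voids per feed mass, kg/kg
    qprime: float  #: specific flow rate q' = Q'/N, 1/min
    tr: float  #: residence time gamma/q', min


def gamma_of(bed: BedSpec) -> float:
    """CO2-to-feed mass ratio held in the bed voids.

    With beads the holdup is computed from the bed volume, ``rho_f*eps*V/N``;
    for a neat alga bed from the void/solid volume ratio,
    ``eps*rho_f/((1-eps)*rho_s)``.
    """
    if bed.with_beads:
        if bed.V is None:
            raise ValueError("bed volume V is required when the bed contains beads")
        return bed.rho_f * bed.eps * bed.V / bed.N
    return bed.eps * bed.rho_f / ((1.0 - bed.eps) * bed.rho_s)


def flow_derived(bed: BedSpec) -> FlowDerived:
    """Derive gamma, q' and tr; the identity q'*tr == gamma holds exactly."""
    gamma = gamma_of(bed)
    qprime = bed.Qp / bed.N
    tr = gamma / qprime
    return FlowDerived(gamma=gamma, qprime=qprime, tr=tr)


def co2_density(P_MPa: float, T_C: float) -> float:
    """Optional hook: CO2 density from an equation-of-state library, kg/m3.

    Requires CoolProp; raises ImportError with guidance when unavailable.
    Density is otherwise a plain user input (``BedSpec.rho_f``).
    """
    try:
        from CoolProp.CoolProp import PropsSI
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "CoolProp is not installed; supply rho_f directly in BedSpec "
            "(e.g. from tabulated CO2 densities)"
        ) from exc
    return float(PropsSI("D", "P", P_MPa * 1e6, "T", T_C + 273.15, "CO2"))
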