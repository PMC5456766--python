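"""Synthetic extraction curves with gravimetric-style measurement noise.

Real extraction curves are measured by interrupting the CO2 flow and
weighing the extract collected since the previous interruption, so the
noise lives on the *increments* of the cumulative yield, not on the
cumulative values.  The generator therefore simulates the model, takes
yield increments between sampling points, perturbs each with multiplicative
Gaussian noise (default 2 % relative), and re-accumulates; the cumulative
curve stays non-decreasing and unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bed import BedSpec, flow_derived
from .lumped import ModelParams, yield_at
from .mass_transfer import scale_tc
from .mixers import simulate_mixers

__all__ = ["ExtractionCurve", "generate_curve", "make_two_flow_design"]


@dataclass
class ExtractionCurve:
    """An observed or simulated extraction curve.

    ``abscissa_kind`` is ``"t"`` (time, min) or ``"q"`` (solvent-to-feed
    ratio, kg/kg); ``values`` is the strictly increasing abscissa and
    ``yields`` the cumulative extract per feed mass, kg/kg.  ``metadata``
    carries free-form provenance (bed data, noise descriptor, seed).
    """

    abscissa_kind: str
    values: np.ndarray
    yields: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.abscissa_kind not in ("t", "q"):
            raise ValueError("abscissa_kind must be 't' or 'q'")
        self.values = np.asarray(self.values, dtype=float)
        self.yields = np.asarray(self.yields, dtype=float)
        if self.values.shape != self.yields.shape or self.values.ndim != 1:
            raise ValueError("values and yields must be 1-D arrays of equal length")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("abscissa must be strictly increasing")
        if np.any(self.yields < 0):
            raise ValueError("yields must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    def times(self, qprime: float | None = None) -> np.ndarray:
        """Abscissa as time, min; needs q' when stored as solvent ratio."""
        if self.abscissa_kind == "t":
            return self.values
        if qprime is None:
            qprime = self.metadata.get("qprime")
        if qprime is None:
            raise ValueError("qprime required to convert a q-abscissa to time")
        return self.values / qprime

    def solvent_ratio(self, qprime: float | None = None) -> np.ndarray:
        """Abscissa as solvent-to-feed ratio q = q'*t, kg/kg."""
        if self.abscissa_kind == "q":
            return self.values
        if qprime is None:
            qprime = self.metadata.get("qprime")
        if qprime is None:
            raise ValueError("qprime required to convert a time abscissa to q")
        return self.values * qprime


def generate_curve(
    p: ModelParams,
    bed: BedSpec,
    sampling,
    noise_sd: float = 0.02,
    seed: int | None = None,
    abscissa_kind: str = "t",
    n: int = 1,
    dt: float | None = None,
) -> ExtractionCurve:
    """Simulate an extraction curve and add gravimetric sampling noise.

    Parameters
    ----------
    p, bed
        Model parameters and the bed they refer to (recorded in metadata;
        ``p`` must already use the gamma/tr this bed implies).
    sampling : array_like
        Strictly increasing sampling abscissa (times in min, or solvent
        ratios when ``abscissa_kind="q"``).
    noise_sd : float
        Relative standard deviation of the multiplicative noise on yield
        increments; 0 returns the exact model curve.
    seed : int, optional
        Seed for the noise stream; identical seeds give identical curves.
    n : int
        Number of mixers; 1 uses the exact lumped solution.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    fd = flow_derived(bed)
    sampling = np.asarray(sampling, dtype=float)
    t = sampling / fd.qprime if abscissa_kind == "q" else sampling
    if n == 1:
        e = yield_at(p, t)
    else:
        traj = simulate_mixers(p, n, dt=dt, t_end=float(t.max()) * 1.001)
        e = np.interp(t, traj["t_min"], traj["e_kgkg"])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        inc = np.diff(np.concatenate(([0.0], e)))
        factors = np.clip(1.0 + rng.normal(0.0, noise_sd, size=inc.size), 0.0, None)
        e = np.cumsum(inc * factors)
    meta = {
        "qprime": fd.qprime,
        "gamma": fd.gamma,
        "tr": fd.tr,
        "Qp_kg_per_min": bed.Qp,
        "N_kg": bed.N,
        "noise_sd": noise_sd,
        "seed": seed,
        "n_mixers": n,
    }
    return ExtractionCurve(abscissa_kind, sampling, e, meta)


def make_two_flow_design(
    p: ModelParams,
    bed: BedSpec,
    flows: tuple[float, float],
    sampling_q,
    noise_sd: float = 0.02,
    seed: int | None = None,
    n: int = 1,
) -> tuple[ExtractionCurve, ExtractionCurve]:
    """Generate the classic two-flow-rate design on a shared q grid.

    Both runs share the bed and equilibrium parameters; the characteristic
    mass-transfer times are linked through the film-resistance scaling
    ``tc ~ Q'^-0.8``, with ``p.tc`` interpreted as belonging to the first
    flow rate.  Plotted against the solvent-to-feed ratio the two curves
    overlap when ``tc << tr`` (the near-equilibrium regime) and separate
    when mass transfer limits the rate.

    Returns one curve per flow rate, both with a ``q`` abscissa.
    """
    if len(flows) != 2:
        raise ValueError("exactly two flow rates required")
    seeds = (seed, None if seed is None else seed + 1)
    curves = []
    for Qp, s in zip(flows, seeds):
        bed_i = BedSpec(
            N=bed.N, Qp=Qp, rho_f=bed.rho_f, eps=bed.eps, rho_s=bed.rho_s,
            V=bed.V, with_beads=bed.with_beads, dp=bed.dp, SE=bed.SE,
        )
        fd = flow_derived(bed_i)
        tc_i = scale_tc(p.tc, flows[0], Qp)
        p_i = ModelParams(
            eq=p.eq, xu=p.xu, tc=tc_i, tr=fd.tr, gamma=fd.gamma, y0=p.y0,
        )
        curves.append(
            generate_curve(
                p_i, bed_i, sampling_q, noise_sd=noise_sd, seed=s, abscissa_kind="q", n=n
            )
        )
    return curves[0], curves[1]
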