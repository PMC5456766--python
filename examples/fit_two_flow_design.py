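"""Recover model parameters from a noisy two-flow-rate design.

Generates synthetic extraction curves at 0.35 and 0.62 g/min sharing the
equilibrium parameters, with tc linked across flows by the film-resistance
scaling, then fits {ys, xt, K, tc} jointly.  Running at two flow rates is
what breaks the solubility/mass-transfer slope degeneracy of a single
curve — though tc itself remains poorly determined this close to the
equilibrium-controlled regime.
"""

import warnings

import numpy as np

from sfekin import (
    BedSpec, EquilibriumParams, FitSpec, ModelParams, fit, flow_derived,
    make_two_flow_design,
)

truth = {"ys": 0.0093, "xt": 0.11, "K": 0.049, "tc": 0.45}
bed = BedSpec(N=1.25e-3, Qp=0.35e-3, rho_f=910.0, eps=0.40, V=5e-6, with_beads=True)
fd = flow_derived(bed)
eq = EquilibriumParams(ys=truth["ys"], xt=truth["xt"], K=truth["K"])
p = ModelParams(eq=eq, xu=0.345, tc=truth["tc"], tr=fd.tr, gamma=fd.gamma)

q = np.linspace(4.0, 120.0, 24)
c1, c2 = make_two_flow_design(p, bed, (0.35e-3, 0.62e-3), q, noise_sd=0.02, seed=42)
print(f"generated {len(c1)}-point curves at 0.35 and 0.62 g/min (2% gravimetric noise)")

with warnings.catch_warnings(record=True) as caught:
    warnings.simplefilter("always")
    spec = FitSpec(curves=[c1, c2], free=("ys", "xt", "K", "tc"), fixed={"xu": 0.345})
    result = fit(spec, n_starts=8, seed=0)
print(result)
print("\nparameter | truth    | estimate | rel. error")
for name, value in truth.items():
    est = result.params[name]
    print(f"{name:>9s} | {value:<8g} | {est:<8.4g} | {abs(est / value - 1):.1%}")
print("\nxt (break location) is pinned sharply; ys and K inherit some ridge "
      "uncertainty; tc is nearly unidentifiable at these residence times.")
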