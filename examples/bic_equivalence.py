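"""Show that the desorption model and the broken-and-intact-cell (BIC)
model are indistinguishable on a single run at fixed flow.

The BIC tail is governed by an internal-diffusion time ti (extraction
*time* controlled); the desorption tail by the partition coefficient
through the solvent-to-feed *ratio*.  Substituting
ti = (1 + gamma*K + tc/tr)/(K*q') makes the two second-period curves
identical — only experiments varying the residence time can separate the
mechanisms.
"""

import numpy as np

from sfekin import (
    BicParams, EquilibriumParams, ModelParams, approx_lumped_curve,
    bic_curve, bic_equivalent_ti,
)

eq = EquilibriumParams(ys=0.0093, xt=0.11, K=0.049)
p = ModelParams(eq=eq, xu=0.345, tc=0.30, tr=2.35, gamma=1.456)

q = np.linspace(0.1, 100.0, 500)
e_model, q1, e1 = approx_lumped_curve(p, q)
ti = bic_equivalent_ti(p.eq.K, p.gamma, p.tc, p.tr, p.qprime)
print(f"break point: q1 = {q1:.1f} kg/kg, e1 = {e1:.3f} kg/kg")
print(f"equivalent BIC internal-diffusion time ti = {ti:.1f} min")

bp = BicParams(xu=p.xu, ys=p.eq.ys, tf=p.tc, ti=ti, q1=q1, e1=e1)
e_bic = bic_curve(bp, p.tr, p.qprime, q)
print(f"max |desorption - BIC| over q in [0.1, 100]: "
      f"{np.max(np.abs(e_model - e_bic)):.2e} kg/kg")
print("the curves coincide to machine precision: a single extraction curve "
      "cannot tell matrix desorption from intra-particle diffusion")
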