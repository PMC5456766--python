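"""Estimate the film mass-transfer time from the packed-bed Sherwood
correlation and rescale a fitted tc between flow rates.

The chain Sh = 0.206 Re^0.8 Sc^0.33 -> kf = Sh D12/dp -> tf = eps/(kf a0)
collapses to a power law in particle size and superficial flow; for finely
ground alga tc ~ tf, so tc scales as dp^1.2 and Q'^-0.8.
"""

from sfekin import MassTransferInputs, scale_tc, sherwood, tf_estimate
from sfekin.mass_transfer import film_coefficient, reynolds, schmidt

mti = MassTransferInputs(
    dp=3e-4, eps=0.40, mu=8e-5, rho_f=910.0, D12=6e-9,
    Qp=0.35e-3 / 60.0, SE=1e-4,
)
Re, Sc = reynolds(mti), schmidt(mti)
print(f"Re = {Re:.3f}, Sc = {Sc:.1f}, Sh = {sherwood(Re, Sc):.3f}")
print(f"film coefficient kf = {film_coefficient(mti):.3e} m/s")
print(f"film characteristic time tf = {tf_estimate(mti):.3f} min "
      f"(the solute needs ~tf to cross the fluid film at this flow)")

tc_slow = 0.45
tc_fast = scale_tc(tc_slow, Qp_ref=0.35, Qp_new=0.62)
print(f"\ntc fitted at 0.35 g/min: {tc_slow:.2f} min")
print(f"tc rescaled to 0.62 g/min: {tc_fast:.3f} min "
      f"(ratio {tc_slow / tc_fast:.2f}, the 'about 1.6x lower' flow-rate rule)")
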