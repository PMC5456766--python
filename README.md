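# sfekin — supercritical-CO₂ extraction kinetics for microalgal lipids

Supercritical CO₂ extracts vegetable-like oils from microalgae far more
slowly than from oilseeds at the same pressure. `sfekin` implements a
kinetic model family that explains this through **lipid adsorption on the
biomass matrix**: as long as the solid-phase oil concentration `x` exceeds
the matrix adsorption capacity `x_t`, free oil dissolves at its solubility
`y_s`; below `x_t` the remaining oil is matrix-bound and equilibrium
follows a linear isotherm `y⁺ = K·x` (with `K < y_s/x_t`). The package is
for process engineers and researchers who need to simulate extraction
curves, estimate the model's parameters from measured yields, or design
experiments that can actually identify them.

## The model

A packed bed is represented as `n` equal mixers in series (`n = 1` is the
lumped ideal mixer, `n → ∞` plug flow). Per mixer `j` (inlet `y₀ = 0`):

    dy_j/dt = n (y_{j-1} − y_j)/t_r + (y_j⁺ − y_j)/t_c
    dx_j/dt = −γ (y_j⁺ − y_j)/t_c
    e(t)    = q′ ∫ y_n dt

with residence time `t_r`, characteristic mass-transfer time `t_c`
(film + internal), CO₂-to-feed holdup `γ = q′·t_r`, specific flow rate
`q′ = Q′/N`, and cumulative yield `e` per kg of dry feed. Only the
**accessible** oil `x_u` — oil in cells opened by the pretreatment —
participates; `e(∞) = x_u`.

For `n = 1` the model has an exact three-period closed form
(`sfekin.lumped`):

1. **constant rate** — `y = y_s·t_r/(t_r+t_c)`, `e` linear, until `x = x_t`;
2. **washing** — exponential washout of dissolved oil at fixed `x = x_t`;
3. **desorption** — a 2×2 linear system with real, negative eigenvalues
   `p₁,₂ = (−S ± R)/2`, `S = 1/t_r + (1+γK)/t_c`; the tail decays with the
   dominant time constant `T₁ = t_r(1 + γK + t_c/t_r)/(γK)`.

Around the core solution the package provides the plug-flow limit and
regime rules (`t_c/t_r < 0.02` equilibrium-controlled, `> 2`
mixing-insensitive), an explicit-Euler cascade integrator (numba-
accelerated), the packed-bed Sherwood correlation
`Sh = 0.206 Re^0.8 Sc^0.33` with the `t_c ∝ d_p^1.2 Q′^−0.8` scaling,
parameter-interaction (ridge) relations, the equivalence map onto the
broken-and-intact-cell (BIC) model, synthetic-curve generation with
gravimetric noise, and multi-start bound-constrained least-squares fitting
with identifiability profiling.

## Worked example

`python examples/simulate_extraction.py` simulates the ground
*Nannochloropsis* sp. reference run (30 MPa, 40 °C, 1.25 g alga with glass
beads in 5 cm³, 0.35 g/min CO₂; `y_s = 0.0093`, `x_t = 0.11`, `K = 0.049`
kg/kg, `t_c = 0.45` min, `x_u = 0.345` kg/kg):

```
gamma = 1.456 kg CO2 per kg feed held in the bed voids
q'    = 0.280 1/min, residence time tr = 5.20 min

constant-rate period ends at t1 = 92.9 min (e1 = 0.223 kg/kg)
washing ends at t2 = 95.3 min; desorption time constant T1 = 84 min
t =     60 min  q =    16.7  e = 0.143 kg/kg  (constant-rate)
t =    300 min  q =    83.9  e = 0.335 kg/kg  (desorption)
t =   1000 min  q =   280.0  e = 0.345 kg/kg  (desorption)
```

The yield climbs linearly while free oil lasts (0.223 kg/kg by the break),
then tails off exponentially as bound oil desorbs, approaching the
accessible content 0.345 kg/kg — oil in cells the grinding never opened is
never extracted. The other examples cover flow-pattern effects
(`flow_pattern_effects.py`), film-resistance estimation
(`estimate_tc.py`), two-flow-rate parameter recovery
(`fit_two_flow_design.py`) and the desorption/BIC equivalence
(`bic_equivalence.py`). A thin CLI mirrors the library:
`sfekin simulate|generate|fit|estimate-tc|compare-bic --config run.yaml`.

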