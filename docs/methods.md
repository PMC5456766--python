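# Methods

## Model and assumptions

`sfekin` models supercritical-CO₂ extraction of a single pseudo-solute
(neutral lipids; co-extracted hydrocarbons and triglycerides are not
resolved) from a packed bed of dry, pretreated microalga. The physical
picture: only cells opened by the pretreatment expose their oil, giving an
accessible content `x_u` (kg oil per kg dry feed); that oil is either free
(dissolving at the solubility `y_s`) or, once the solid concentration
falls below the adsorption capacity `x_t`, matrix-bound and released along
a linear isotherm `y⁺ = K·x`. The constraint `K < y_s/x_t` keeps the
isotherm below the solubility plateau so the equilibrium law is
non-decreasing. `K = 0` is admitted as irreversible binding: the bound
fraction `x_t` is then reported as unextractable residue.

Transport uses two characteristic times: the residence time
`t_r = γ/q′` of CO₂ in the bed voids and a lumped mass-transfer time
`t_c = t_f + t_i` (film plus intra-particle). Axial dispersion is
described solely by the number of mixers `n`; no explicit dispersion
coefficient exists in the model. The solvent holdup `γ` comes from the bed
geometry: `γ = ε ρ_f/((1−ε)ρ_s)` for a neat bed, `γ = ρ_f ε V/N` when the
alga is diluted with glass beads. Isothermal, isobaric, constant-flow
operation is assumed throughout; CO₂ density is a user input (an optional
CoolProp hook exists but nothing requires it).

## Analytic lumped solution

For `n = 1` the solution is piecewise closed-form. The default
"quasi-steady start" re-initializes the fluid at `y = y_s t_r/(t_r+t_c)`
(the initial transient decays with time constant `t_c t_r/(t_c+t_r)`,
usually well under a minute); `exact_start=True` keeps the transient from
the true `y0`, and the solver falls back to the exact transient
automatically whenever the quasi-steady shortcut would be unphysical
(holdup `γ·y_qss` exceeding the free-solute excess, i.e. a computed
`t₁ ≤ 0`). The desorption period is solved by spectral decomposition of
the 2×2 system matrix; the discriminant equals
`(1/t_r + (1−γK)/t_c)² + 4γK/t_c²`, so both eigenvalues are always real
and negative (a numerically clipped square root guards the roundoff
tail). The yield in that period is evaluated from the conservation law
`x + γy + e = const`, which therefore holds to machine precision by
construction; the state variables themselves follow the A/B
exponential-difference form. Dispatch between period structures follows
the initial state: `x₀ > x_t` gives up to three periods, `x₀ = x_t` with
`K x_t < y₀ ≤ y_s` starts at washing, anything else is desorption-only.
Period boundaries are assigned half-open so the trajectory is continuous;
the boundary `x = x_t` itself evaluates to the free-solute branch,
matching the `x ≥ x_t` inequality of the equilibrium law.

## Numerical cascade

The n-mixer model is integrated by explicit Euler — deliberately, because
the equilibrium law is discontinuous at `x_t` and smooth-stepper error
control is unreliable across the switch. The branch is re-evaluated per
mixer at step boundaries without sub-step event location; the O(dt)
switching error is covered by an enforced stability bound
(`dt < min(t_r/n, t_c)/2`, default `min(t_r/n, t_c)/50`) and a convergence
test asserting first-order error decay against the closed form. The
stepper is numba-compiled with a pure-Python fallback. The yield integral
uses the trapezoid rule on the outlet concentration. Instability
(negative or non-finite concentrations) raises with a suggested smaller
step. Plug flow in the desorption phase is realized as a 100-mixer
cascade rather than a second PDE integrator with identical physics; the
free-solute plug-flow period has its own closed form with a validity
horizon (first time the inlet-end solid reaches `x_t`).

## Mass-transfer estimates

The film time uses `Sh = 0.206 Re^0.8 Sc^0.33` with `Re` built on the
superficial mass flux `Q′/S_E` and the packed-sphere specific surface
`a₀ = 6(1−ε)/d_p`; with those conventions the collapsed power-law
constant is exactly `6 × 0.206 = 1.236` and the diffusivity exponent is
−0.67, which the suite asserts by evaluating the Sh→k_f→t_f chain
independently. All inputs are SI; `t_f` is reported in minutes. The
internal time `t_i` is a fitted or assumed input — pore-diffusion theory
is out of scope. `scale_tc` transfers a fitted `t_c` between runs as
`d_p^1.2 Q′^−0.8`, valid when `t_i` is negligible (finely ground alga).

## Synthetic data

The generator emulates gravimetric sampling: the model curve is evaluated
at the sampling times, and each yield *increment* is multiplied by
`1 + N(0, σ)` (default σ = 2%, clipped at zero), mirroring weighing of the
extract collected between flow interruptions. Cumulative curves stay
non-decreasing and unbiased; everything is deterministic given a seed.
The two-flow design generator shares the equilibrium parameters and links
`t_c` across flows by `scale_tc`. What it does **not** emulate: flowmeter
drift, separator losses, temperature/pressure excursions, multi-solute
selectivity, or heteroscedastic weighing error — so passing recovery
tests demonstrate estimator correctness under the model's own noise
assumptions, not robustness to real-world systematic error.

## Parameter estimation and identifiability

Fitting is bound-constrained least squares (scipy TRF) on the cumulative
yield, with a data-driven first start plus log-uniform random multi-starts
(default 8, seeded). The equilibrium constraint `K < y_s/x_t` is enforced
by clipping with a penalty residual rather than a hard failure, keeping
iterates usable on infeasible excursions. Standard errors come from the
Gauss–Newton curvature. Losses are unweighted by default (cumulative
yields are roughly homoscedastic); a relative option exists. `n` is never
relaxed continuously: it is chosen by discrete search, with ties broken
toward the smallest `n` within a tolerance band scaled to the observed
yields.

Identifiability is structural, not incidental: the period-1 slope fixes
only `y_s/(1+t_c/t_r)` (mixer) or `y_s(1−e^{−t_r/t_c})` (plug flow), and
the desorption tail fixes only `T₁`, which couples `t_c` and `K`; `K`
moreover enters only as `γK`, so an assumed (rather than measured) `γ`
biases it one-for-one. The fitter warns in these situations and
`profile_identifiability` re-fits along a parameter grid to expose flat
directions. A quantitative consequence, measured by the package's own
simulation study (two flows 0.35/0.62 g/min, `t_c = 0.45` min,
`t_r ≈ 5` min, 2% noise, 100 replicates): medians ≈ 1% for `x_t`, ≈ 9%
for `y_s`, ≈ 10% for `K`, but ≈ 100% for `t_c` — at these short
mass-transfer times relative to residence time the design sits near the
equilibrium-controlled regime and the data contain almost no `t_c`
information; the corresponding recovery test records this honestly rather
than papering over it. Identifying `t_c` requires designs with larger
`t_c/t_r` (coarser particles or faster flow).

## Numerical choices and problem sizes

Defaults: ε = 0.35 (neat bed) / 0.40 (with beads), ρ_s = 950 kg·m⁻³, all
overridable; internal units kg/min/kg·kg⁻¹ with converters only at the
I/O boundary. Oracle-equivalence tests compare the analytic solution with
the Euler cascade at `dt = 10⁻³` min over the fitted parameter sets of
the two reference algae, on horizons of `t₂ + 3T₁` capped at 400 min
(low-`K` rows have `T₁ ≈ 10³` min; longer horizons add no information to
a sup-norm check while multiplying cost). The desorption point-check uses
an independent test-local Euler oracle at `dt = 10⁻⁵` min so the oracle's
own first-order error sits below the 10⁻⁶ comparison tolerance. The
recovery study uses 24-point curves and 2 starts per replicate, sizes
chosen to mirror realistic gravimetric campaigns while keeping the whole
suite fast.

## Known limitations

Single pseudo-solute; no pressure-drop, thermal or density-profile
modelling of the bed; no prediction of the equilibrium parameters'
pressure/temperature trends (they are inputs or fit targets); no Bayesian
uncertainty; the BIC comparison covers only the approximate two-period
BIC curve, not a full BIC model with its own internal-diffusion
mechanics. The washing-period approximation in the two-period comparison
curve drops a finite (if short) period and is accurate to a few percent
of `x_u` at the reference conditions.
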