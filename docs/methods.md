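# Methods

This document records the mathematical model implemented by `tumorgl`, the
conventions and numerical choices made, the design of the synthetic data
generator, and the known limitations of the procedures. Symbols follow the
code (`a`, `k`, `N0`, `alpha`, `beta`, `gamma`, `delta`, `tau`, `Y0`).

## 1. Growth model

Untreated tumor burden `N(t)` (volume in mm³, cell count, or diameter in mm —
the model is agnostic, the unit travels with the trajectory) follows the
Gompertz law

```
dN/dt = f(N)·N,     f(N) = a − k·ln(N/N0) = k·ln(N∞/N),
```

with growth-rate coefficient `a` (day⁻¹), decay coefficient `k` (day⁻¹), and
carrying capacity `N∞ = N0·exp(a/k)`. In log size `u = ln N` the equation is
linear, `du/dt = a − k(u − u0)`, with the closed form

```
u(t) = u0 + (a/k)·(1 − e^{−k(t−t0)}).
```

For `|k| < K_EPS = 1e−9` the code branches to the exponential limit
`u = u0 + a·(t − t0)` rather than evaluating `0/0`; the property
`effective_carrying_capacity` returns `None` in that regime. Negative `(a, k)`
pairs are admitted and describe an *extinction* regime in which the decay rate
itself accelerates — useful for post-therapy depletion.

A second rate law is provided for terminal decay phases, with the rate linear
in time rather than in log size:

```
du/dt = a·(t − t0) − k·(u − u0)   ⇒   u = u0 + (a/k)·[ s − (1 − e^{−ks})/k ],  s = t − t0,
```

(`a` then has units day⁻²; the `k → 0` limit is `u0 + a·s²/2`). Fits using it
are flagged by `a_linear_time=True`.

All therapy algebra is done in `u`-space, where kills are subtractions and the
homogeneous dynamics are linear, so effects superpose exactly.

## 2. Radiotherapy

A fraction of dose `d` (Gy) kills by the linear–quadratic (LQ) model:
surviving fraction `exp(−αd − βd²)`, i.e. an instantaneous log-kill
`αd + βd²`. Defaults in the bundled designs use `α = 0.3 Gy⁻¹` and the common
convention `β = α/10`. Kills are applied **right-continuously**: `N(t_i)` is
the post-kill value, and simulation grids that contain a fraction time report
the post-kill size at that point.

Because the log-space dynamics are linear, a kill delivered at `t_i` has, by a
later time `t`, been partially regrown away; its remaining contribution is the
exponentially discounted log-kill `(αd_i + βd_i²)·e^{−k(t−t_i)}`. A course of
`n_f` fractions therefore contributes

```
D_nf(t) = Σ_{t_i ≤ t} (α d_i + β d_i²) · e^{−k (t − t_i)}.
```

Fraction times must be non-decreasing (two fractions may share a time, which
composes their kills); they must lie inside the evaluation window for the
scalar `combined_log_effect`, while grid evaluation (`course_log_size`) simply
masks future fractions.

## 3. Immunotherapy

Immunotherapy enters as a kill-*rate* term `−γ·I(t)` on the specific growth
rate, with efficacy `γ` and infusion profile `I(t)`. The accumulated,
regrowth-discounted log-effect over `[t0, t]` is

```
W̄(t) = γ ∫_{t0}^{t} e^{−k(t−s)} I(s) ds,
```

evaluated in closed form for the two supported profiles (Δ = t − t0):

- constant `I(s) = I0`:            `W̄ = γ I0 (1 − e^{−kΔ}) / k`;
- exponential `I(s) = I0 e^{−ρ(s−t0)}`: `W̄ = γ I0 (e^{−ρΔ} − e^{−kΔ}) / (k − ρ)`,
  with the limit `γ I0 Δ e^{−kΔ}` when `|k − ρ| < K_EPS`.

Both closed forms are verified against adaptive quadrature in the tests.

## 4. Combined course and the regression criterion

Over `[t0, t]` the log-size change under a combined course is, exactly,

```
u(t) − u(t0) = G(t0, t) − W̄(t) − D_nf(t),
```

where `G` is the untreated Gompertz log-gain. The tumor has regressed below
its size at `t0` iff the **margin** `G − W̄ − D_nf` is negative;
`regression_condition` returns this margin, the boolean verdict, and a
`near_critical` flag when `|G − D_nf| ≤ tol` (default `tol = 0.05` in log
units, i.e. within ~5 % in size) — near the threshold the verdict is
noise-sensitive and should not be over-interpreted. The identity itself is
tested to ≤ 1e−8 in log size against a high-accuracy ODE integration of the
same course, so the criterion is a statement about the model, not an
approximation.

### Worked value

For `a = 0.054`, `k = 0.0164`, `N0 = 50`, three 8 Gy fractions on days
9/10/11 (`α = 0.3`, `β = 0.03`), evaluated at day 15:
`G = 0.7181`, `D_nf = 11.9408`, margin `−11.2227` → regression. The
per-fraction log-kill is `0.3·8 + 0.03·64 = 4.32`; the three discounted kills
sum to slightly less than `3 × 4.32 = 12.96` because of regrowth discounting.

## 5. Abscopal / synergy model

An unirradiated metastasis receives no dose; instead, each fraction delivered
to the primary at `t_i` triggers a delayed, decaying immune pulse on the
metastasis' specific rate:

```
du/dt = a − k(u − u_in) − δ · Y0 · Σ_{t_i} H(t − t_i − lag) · e^{−(t − t_i − lag)/τ},
```

with coupling strength `δ` (dimensionless switch/scale), pulse amplitude `Y0`
(day⁻¹), onset delay `lag` (days) and decay time `τ` (days). A single
"immune response delay/decay" timescale is often quoted for such models; this
implementation splits it into an onset lag and a decay constant and defaults
`lag = τ` so that a single-timescale description is recovered by specifying
only `τ`. `t_in` anchors the untreated phase (it must not exceed the first
fraction time).

The trajectory has three phases:

1. **Before the first pulse onset** — exact untreated Gompertz.
2. **Pulsed phase** — the rate equation is integrated numerically
   (`solve_ivp`, RK45, `rtol = 1e−10`) from the first onset to the last
   fraction time + `lag`; there is no closed form once pulses overlap the
   log-linear regrowth.
3. **After the last pulse onset** — the specific rate at the end of phase 2
   is evaluated; if it is negative the lesion is continued as a frozen
   exponential decay at that rate (`r_end`, evaluated `1e−6` days past the
   onset to stay on the post-onset branch), otherwise integration continues.
   Freezing reflects the modeling choice that a lesion driven into depletion
   by the immune response keeps its terminal decay rate rather than
   re-saturating.

`δ = 0` or `Y0 = 0` short-circuits to the exact untreated closed form, and the
tests check that sizes are pointwise non-increasing in `Y0`, `δ`, and `τ`.

## 6. Effective-parameter fitting

Given observations `(t_j, N_j)`, `fit_gompertz` estimates `(a_eff, k_eff)` by
nonlinear least squares **on log size** (default; raw-size residuals are
available via `log_residuals=False`). Choices and rationale:

- **Objective on log size.** Tumor measurement noise is predominantly
  multiplicative; log residuals make it homoscedastic and keep late, large
  sizes from dominating.
- **`N(t0)` fixed to the first observation** by default (matching the usual
  practice of anchoring at the first measurement); `fit_n0=True` co-estimates
  it instead, which reduces small-sample bias in `k` at the cost of a third
  parameter.
- **Multi-start Levenberg–Marquardt.** Starts are the Cartesian grid
  `a ∈ {0.01, 0.05, 0.1, 0.3}` × `k ∈ {±0.005, ±0.05, ±0.3}` plus a
  data-driven first guess from the initial slope; the solver exits early when
  four starts agree to 1e−6 relative SSR or an exact fit is found. This makes
  the sign of `k` (saturating vs extinction) an outcome of the fit, not of the
  initialization.
- **Uncertainties** are the χ²/dof-scaled standard errors from the Gauss–
  Newton covariance `(JᵀJ)⁻¹` at the optimum. Fits with
  `cond(JᵀJ) > 1e12`, or constant data, are flagged `degenerate` with `None`
  errors rather than reporting meaningless numbers.
- **Goodness of fit**: Pearson correlation between observed and fitted sizes,
  and the RMS relative error `sqrt(mean(((obs − fit)/fit)²))`.
- At least 4 observations are required per fit (2 parameters + 2 dof).

**Phase-wise fitting** (`fit_phasewise`) splits a trajectory at user-supplied
break times and fits each phase separately; each phase after the first is
anchored to the *previous phase's fitted value at its last observation time*,
so phases join continuously and no fitted curve is extrapolated beyond its own
data. The last phase can use the linear-in-time rate law
(`linear_a_last_phase=True`), appropriate for accelerating post-therapy decay;
`phase_sign_pattern` summarizes the per-phase signs of `(a_eff, k_eff)`, whose
transition to `(−, −)` is the depletion signature.

**Day-by-day specific rate** (`estimate_specific_rate`) is the central
difference `d(ln N)/dt` via `np.gradient` (second-order on interior points;
a forward-difference option exists). The convergence tests confirm the
expected second-order behavior.

## 7. Synthetic data generator

The generator exists to provide ground truth for the fitting machinery and to
emulate the *shape* of two study archetypes, not their biology:

- `antibody_like_design`: five arms (untreated, two agonist doses, two
  antagonist doses) with effective parameters around the untreated pair
  `a = 0.049`, `k = 0.011 day⁻¹`, `N0 = 100`, observed every 2 days over days
  0–40 — agonist arms have larger `a`, antagonist arms smaller, while `k`
  stays near the untreated value.
- `rt_abscopal_like_design`: untreated, 1 × 8 Gy, 3 × 8 Gy, and an
  unirradiated-metastasis arm, at `a = 0.054`, `k = 0.0164 day⁻¹`, `N0 = 50`,
  daily observations over days 0–25.

Noise is multiplicative lognormal by default, `N_obs = N·exp(ε)`,
`ε ~ Normal(0, sd)`, `sd = 0.05` (a typical few-percent caliper/imaging
error); additive Gaussian noise is available and resamples non-positive draws.
Seeding uses `numpy.random.default_rng([seed, indices...])` so that each
(arm, subject) or (seed, replicate) pair gets an independent, reproducible
stream, and reseeding one arm never perturbs another.

What the generator does **not** emulate: inter-subject parameter
heterogeneity (all subjects in an arm share the generating parameters —
replicate spread is measurement noise only), dropout/censoring, detection
limits, irregular visit schedules, and any immunological mechanism beyond the
macroscopic kill-rate terms above.

The bundled three-phase trajectory (`three_phase_rt_trajectory`) uses phases
`(a, k) = (0.25, 0.12)`, `(0.08, 0.4)`, and `(−1e−3, −0.3)` (last phase
linear-in-time) with breaks at days 12 and 22 over days 0–36. These values
were chosen *a priori* so that each phase's `k` is identifiable from ~11–15
daily observations at 5 % noise (`k·Δt` of order 1 within each phase); with
weaker curvature the per-phase sign of `k` is not recoverable at this noise
level — which is a statement about identifiability, not about the fitter (see
§9).

## 8. Numerical verification

- Closed-form growth, course, and IT expressions are validated against
  `scipy.integrate.solve_ivp` (RK45, `rtol = 1e−11`, `atol = 1e−12`) on the
  log-size ODE with segment-wise event handling at fraction times; agreement
  is ≤ 1e−6 relative (typically ~1e−11) across 200 randomized configurations.
- The multi-fraction identity of §4 holds to ≤ 1e−8 in log size across 100
  randomized schedules.
- The regression criterion's sign agrees with direct simulation in 500/500
  randomized cases (near-critical cases are excluded by construction, since
  there the sign is ill-conditioned by definition).
- Fitting recovers noiseless data to 1e−6 relative across random draws, and
  the standard errors shrink with sample size at the expected ~`1/√n` rate.

## 9. Known limitations

- **`k` identifiability depends on the design.** For the fibrosarcoma
  tumor-size design (`a = 0.054`, `k = 0.0164`, 26 daily points), `k·T ≈ 0.4`
  over the observation window: the curvature signal is weak relative to 5 %
  noise, the NLS estimate of `k` is right-skewed, and the 100-replicate mean
  overshoots the generating value by ~10–14 % (less when `N0` is
  co-estimated). This is an intrinsic property of the design, not a solver
  artifact — the same machinery recovers `k` to within ~2 % on the
  antibody-study design, where `k·T ≈ 0.45` but twice the dynamic range in
  log size is observed. Mean `a` recovery is at the ~1 % level on all bundled
  designs. The acceptance script therefore reports mean `a` for all three
  designs but mean `k` only where the design identifies it.
- The regression criterion evaluates the *deterministic* model; stochastic
  extinction of small residual populations is outside scope (sizes below one
  cell are reported as-is).
- The abscopal pulsed phase has no closed form; it is integrated numerically,
  and the frozen-exponential continuation is a modeling choice (see §5).
- LQ parameters are taken as known when simulating; the fitting machinery
  estimates effective growth parameters per phase, not `α`, `β`, `γ`, or the
  synergy parameters.
- The χ²/dof-scaled errors assume independent, identically distributed
  residuals; autocorrelated measurement error would make them optimistic.
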