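# Methods

## Scope and intent

`adpkdsim` simulates lifetime renal-function decline in ADPKD patients
characterised only by published cohort summary profiles (mean age, %
female, mean eGFR, mean TKV), applies a proportional tolvaptan effect to
the decline rate, and reports time-to-ESRD outcomes. Post-ESRD care
(dialysis/transplant modalities), costs and utilities, TKV treatment
benefit, kidney-pain endpoints and extra-renal disease are out of scope.

## Progression law

The published outcome numbers this package reproduces were generated by
a proprietary simulation whose trajectory equations are not public, so
the law here is this package's own construction, chosen to satisfy the
qualitative constraints the published material does fix — trajectories
are non-linear functions of baseline age, sex, TKV and eGFR; decline
accelerates over time; the model admits a constant proportional
treatment effect on the decline rate — and then shown to reproduce the
published outcomes quantitatively (see Calibration and Validation).

* TKV: exponential growth `TKV(t) = TKV₀ e^{g t}`, with
  `g = ln(TKV₀/(150·h))/a₀` back-extrapolated from the 150 mL/m
  height-adjusted reference at age zero, exactly as the Mayo imaging
  classification assumes (there with annual compounding; here the
  continuous-rate analogue so the trajectory is smooth).
* eGFR: instantaneous decline `κ·(TKV/1000)^γ`, multiplied by `1−ρ` on
  treatment. With `a = γ·g` and `κ' = κ·(TKV₀/1000)^γ` the closed form
  is `e(t) = e₀ − m·(κ'/a)(e^{a t} − 1)`, with the linear limit used
  when `a < 1e−10`, and the ESRD crossing time
  `T = ln(1 + Δ·a/(m·κ'))/a`, `Δ = e₀ − 15`. Piecewise-constant
  multipliers (treatment start/stop, washout, discontinuation) compose
  segment by segment, still in closed form.
* eGFR never rises. The transient haemodynamic eGFR shifts observed at
  tolvaptan initiation and withdrawal in trials are deliberately not
  modelled; the treatment effect is purely a slope reduction.
* Sex enters through height only (via the htTKV reference); no
  sex-specific decline modifier is applied because no sex-specific
  inputs are published.

Parameters and defaults: κ (fitted, ≈3.49 mL/min/1.73 m²/yr at the
1000 mL normalising volume), γ (fitted, ≈0.42, dimensionless), ESRD
threshold 15 mL/min/1.73 m² (KDIGO stage-5 boundary), htTKV reference
150 mL/m, eGFR floor 0.

## Mortality

Background death uses a Gompertz–Makeham hazard
`scale·(λ + A·e^{B·age})` with λ = 2·10⁻⁴/yr, A = 2.5·10⁻⁵/yr,
B = 0.095/yr — a standard adult all-cause shape — and a single fitted
scale. The scale multiplies the whole hazard so that a target ESRD
fraction of 1 corresponds exactly to scale 0 (no mortality). A patient
"reaches ESRD" iff the eGFR crossing precedes death; exact continuous
event times decide, with measure-zero ties broken to ESRD-first.

## Cohort synthesis

Profiles are shipped verbatim as a CSV fixture. Two modes:

* **mean** — every patient at the profile means; sex split matches the
  female percentage to integer rounding; fixed heights 1.63 m (F) /
  1.76 m (M). Deterministic, no RNG consumed. Expectation-mode
  evaluation collapses this to two sex strata weighted by the female
  fraction.
* **stochastic** — age and eGFR from truncated normals (CV 0.15 and
  0.25; bounds 18–90 yr and (16, 150) mL/min/1.73 m²), TKV log-normal
  (CV 0.45) truncated above 1.05× the reference kidney volume so every
  patient has a positive growth rate, heights truncated normal
  (SD 0.06/0.07 m, bounds 1.40–2.10 m). The published tables print
  standard errors of means, not patient-level dispersions, so these CVs
  are configuration chosen to span typical ADPKD heterogeneity; all
  headline results use mean mode and are unaffected by them.

What the generator does *not* emulate: correlation structure between
age, TKV and eGFR; non-lognormal TKV tails; measurement error;
enrolment-driven selection beyond the printed means. Passing tests
therefore demonstrate internal consistency and reproduction of
published cohort-level outcomes, not patient-level realism.

The Mayo subclass operation bins the annualised compound htTKV growth
rate at 1.5/3/4.5/6 %/yr with boundary ties assigned upward (arbitrary
but fixed); a 10⁻¹³ snap tolerance absorbs floating-point round-off at
exact boundaries without affecting any physically distinguishable rate.

## Treatment layer

The effect table holds the nine published (measure, subgroup)
combinations; any other lookup raises. Treatment affects only the eGFR
decline multiplier, never TKV growth. Discontinuation is permanent, its
annual hazards apply per treatment-year (0.50% extrapolated from year 4
onward), and stopping times sit mid-year within the stopping year — an
unbiased within-year convention made explicit because only annual rates
are published. The base case applies no discontinuation. An in-trial
override can replace the first three years with the observed trial
trajectories (piecewise-linear cumulative TKV change, constant arm
slopes), after which the model law resumes from the overridden state
with the baseline growth rate retained.

## Calibration

Two progression anchors — overall-cohort natural time to ESRD 13.3 yr
(age 52 from 38.7) and treated delay 5.1 yr at ρ = 0.316 — identify
(κ, γ): for fixed γ the natural-time equation pins κ (time strictly
decreasing in κ, bracket [0.5, 20]); the delay misfit is then strictly
decreasing in γ (bracket [10⁻⁹, 2], the γ→0 limit bounding the
achievable delay above by Δ·ρ/((1−ρ)·κ')), so nested Brent iterations
find the unique root to 10⁻¹² without initial guesses. The mortality
scale then solves the 96%-reach-ESRD equation by bracketed
root-finding. Calibration is deterministic, idempotent, and finishes in
well under a second; infeasible anchors raise a diagnostic error rather
than returning a least-bad fit. Anchors are evaluated on the same
sex-stratified mean profile the scenario runner uses, so the anchor
outcomes reproduce to solver precision in reported summaries.

The published three-year trial slope (−3.812 mL/min/1.73 m²/yr placebo)
is deliberately *not* an anchor: it is a trial-period average under
trial conditions, available through the in-trial override scenario; the
calibrated instantaneous initial decline for the overall profile is
steeper (≈4.4).

## Outcome definitions

* Delay to ESRD: treated-minus-control difference in mean age at ESRD
  onset **among patients reaching ESRD** (each arm's conditional mean).
  An all-patient restricted-mean ESRD-free-time (`rmst_to_esrd`) is also
  emitted for users who prefer an unconditional contrast, but headline
  delays use the conditional definition.
* Treatment duration: expected alive-years on treatment truncated at
  ESRD, death or discontinuation, integrating the survival function
  over the on-treatment intervals (quadrature via `scipy`).
* ESRD prevented: control-arm minus treated-arm fraction reaching ESRD
  before death.
* Kaplan–Meier curves use `lifelines` with death as censoring; in
  expectation mode each stratum contributes an event atom weighted by
  its survival-to-ESRD probability and a complementary censored atom.

## Numerical choices and degenerate inputs

Closed forms are exact, so the only tolerances are solver ones (Brent
10⁻¹², quadrature defaults). A monthly explicit-Euler integration of
the decline ODE is kept in the test suite as an independent check on
the closed form (agreement within 0.1 mL/min/1.73 m² over 30 years for
all shipped profiles). Patients at or below the reference kidney volume,
non-positive ages, eGFR at or below the ESRD threshold, multipliers
outside (0, 1] and reversed age intervals are rejected with explicit
errors. Stochastic modes consume a single `numpy` Generator seeded from
the scenario seed, making runs bit-reproducible.

## Problem sizes

Expectation mode evaluates two strata (plus up to ~70 discontinuation
atoms) per scenario, a few milliseconds each. Stochastic checks in the
test suite use 10⁵ draws for distribution-level comparisons and
300–10⁴-patient cohorts for scenario-level ones — sizes at which
Monte-Carlo error is comfortably below the tolerances being asserted.

## Known limitations

* The trajectory law is a stand-in constructed from published
  constraints; equivalence with the original proprietary model is
  claimed only at the level of the published outcome numbers, all of
  which are reproduced within the stated tolerances.
* Mortality is background-only (no CKD-stage excess hazard); the scale
  calibration absorbs level error but not shape error.
* The treatment effect is constant for life; effect waning, adherence
  short of full discontinuation, and re-initiation are not modelled.
* Subgroup cohorts are built from their own published rows, not by
  filtering a heterogeneous overall cohort, so cross-subgroup patient
  overlap is not represented.
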