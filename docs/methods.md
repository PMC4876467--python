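# Methods

## The analysis problem

One temporal lobe is the analysis unit. Each lobe carries a cumulative DVH,
15 dosimetric scalars derived from it, four clinical covariates (age, sex,
T-stage dichotomized T1-2 vs T3-4, chemotherapy yes/no), a follow-up time in
months from the end of radiotherapy, and an outcome: MRI-detected injury at
its latency time, or censoring (death, repeat radiotherapy, or end of
follow-up). Both lobes of a patient are treated as independently at risk
given their own dose — the bilateral-independence assumption. Censoring by
death and repeat RT acts at the patient level; no competing-risks model is
fitted (death is plain censoring).

## DVH conventions (`dvh`)

Curves are cumulative — volume (cc) receiving **at least** each dose (Gy);
differential DVHs are rejected. Volumes `V_x` are absolute cc, not percent.
`D_max` is the largest dose coordinate of the curve (point-dose at the
curve's own resolution; no D2%-style surrogate). Lookups interpolate
linearly in both directions; within a flat (tied-volume) segment the largest
dose is returned, and `dose_at_volume(0)` returns `D_max`. Mean dose is
`(1/TLV)·∫V(d)dd` by the trapezoid rule over the tabulated curve; median dose
is the inverse lookup at `TLV/2`. All doses are physical; no LQ/EQD2
fractionation conversion is applied anywhere (tolerance doses are tied to the
cohort's ~33-fraction background). `D_xcc` levels above the structure volume
fall back to the lowest tabulated dose. Degenerate structures (zero volume)
are an error.

## Synthetic cohort (`simulate`)

The generator emulates the structure of a 132-patient bilateral cohort:

- **DVH shape.** `V(d) = TLV·(1 − d/D_max)^a` on a 0.1-Gy grid. The
  shoulder exponent `a ~ N(2.1, 0.25)` sets mean dose ≈ `D_max/(a+1)`;
  `TLV ~ N(100, 13)` cc clipped to the observed span (67–137.8);
  `D_max ~ N(70.5, 5)` Gy clipped to 56.1–83.1. Clip bounds and moments are
  calibrated so the per-variable mean/min/max of a default cohort falls
  inside the published per-variable envelopes. Because all hot-spot metrics
  derive from the same `(D_max, a)` pair, `D_max`, `D_0.1cc` and `D_1cc` are
  strongly rank-correlated (Spearman ρ ≈ 0.9), reproducing the collinearity
  that motivates penalized selection.
- **Left-right correlation.** A patient latent severity `z_p` enters each
  lobe as `√c·z_p + √(1−c)·ε`, giving within-patient `D_max` correlation `c`
  (default 0.75).
- **Outcome.** Proportional hazards in `D_1cc`:
  `h(t|D) = h₀(t)·exp(β·D)` with Weibull baseline parameterised by its
  60-month log cumulative hazard. Defaults `β = 0.16072 /Gy`,
  `ln H₀(60) = −13.1600` are the values implied by 60-month failure
  probabilities of 5% at 63.4 Gy and 50% at 79.6 Gy; Weibull shape 2.0 puts
  the median observed latency in the low-to-mid 40s of months. Latency is
  drawn by inverting the conditional survival function, so latency and dose
  are coupled exactly as the Cox model assumes.
- **Censoring.** Follow-up uniform on 11–106 months (administrative; injury
  is never observed past it). Death with probability 0.17 (time uniform
  6–90 months) and repeat RT with probability 0.08 (11–72 months) act on both
  lobes; the observed time is the minimum of latency, follow-up and censor
  time, with the reason recorded. In expectation ≈ 20 patients are censored
  by death/repeat RT before 50 months, matching the scale of the published
  exclusion count (21).
- **Clinical covariates** are marginal (male 0.73, chemo 0.856, T3-4 0.606,
  age N(47,12) clipped 12–77) and independent of dose by default; an optional
  `t_stage_dose_link` ties stage to the dose latent to emulate confounding.
- **Reproducibility.** Per-patient substreams are spawned from one master
  seed, so cohorts regenerate identically and are stable under partial
  regeneration.

What the generator does **not** emulate: a hard latency ceiling (real
injuries cluster below ~50–68 months, while a Weibull proportional-hazards
model keeps a late tail), spatial dose information beyond the DVH, imaging
cadence, and tumour-control endpoints. Passing tests therefore show the
statistical machinery is correct under the assumed model, not that the model
captures every feature of clinical data.

## Elastic-net Cox screen (`coxnet`)

The penalized objective is
`−(1/n)·logPL(β) + λ·[α‖β‖₁ + (1−α)/2·‖β‖₂²]` with α = 0.5 and Breslow tie
handling. It is minimised by cyclic coordinate descent on the iteratively
reweighted quadratic approximation (diagonal Hessian), with warm starts along
a geometric λ path from `λ_max` (smallest λ with all coefficients zero,
inflated by 1e-9 so the path head is exactly null) down to `λ_max/100` over
50 points. Predictors (including 0/1-coded categoricals) are standardized
internally; coefficients are reported on the original scale. Numerical
choices: convergence at max coefficient change < 1e-7 (standardized scale),
at most 1e5 sweeps, an active-set strategy between full sweeps, a
step-halving safeguard that makes the penalized objective non-increasing
across IRLS steps, and an optional numba-compiled kernel (pure-Python
fallback). KKT subgradient residuals are exposed for verification.

Cross-validation uses K = 10 folds split at the **patient** level (both
lobes share a fold — the conservative choice given within-patient
dependence) and stratified by patient event status; a held-out fold with no
events triggers a re-draw with a new sub-seed. The CV loss is
partial-likelihood deviance in the Verweij–van Houwelingen form,
`dev_k = −2·[logPL_all(β^(−k)) − logPL_train(β^(−k))]`, normalized per
held-out event and averaged with event weights (the glmnet convention —
without this normalization the 1-SE band absorbs fold-size variance and the
rule collapses to the null model). `λ` is chosen by the 1-SE rule by
default; the plain minimum is available. The "mean squared error" wording
sometimes attached to Cox cross-validation is a software-UI artifact;
deviance is the statistically meaningful loss and is what is implemented.

At the study's size (~14 injured lobes among 264) the 1-SE set is often
empty and, when non-empty, falls in the hot-spot cluster; this conservatism
is a property of the data scale, not of the solver, and larger cohorts
select the cluster stably.

## Cox dose-response route (`coxmodel`)

The definitive univariate fit uses Newton–Raphson on the partial likelihood
with **Efron** tie handling (more accurate with monthly-grained ties;
Breslow is used inside the penalized path — the two differ only through
ties). The Breslow baseline cumulative hazard is computed at covariate zero,
`H₀(t) = Σ_{s≤t} d_s / Σ_{j∈R_s} e^{βx_j}`, and evaluated as a step function
at the largest event time ≤ t; requests beyond the last observed time are an
extrapolation error. The failure function and its closed-form inverse are

`F(t|D) = 1 − exp(−H₀(t)·e^{βD})`, `TD_p = [ln(−ln(1−p)) − ln H₀(t*)]/β`,

with the horizon fixed at t* = 60 months by default. A degenerate
(constant-dose) covariate yields β = 0 with infinite SE and a warning; a
monotone partial likelihood (hazard ratio across the observed dose range
above e²⁰) is flagged.

TD standard errors on this route are **approximate** delta-method values
propagating Var(β), the martingale variance of the Breslow estimator
`Σ d_s/W_s²`, and their covariance through `dH₀/dβ = −Σ d_s·S1_s/W_s²`
(`S1_s = Σ_{R_s} x e^{βx}`). The β–H₀ covariance term is essential: the two
estimates are strongly negatively correlated and ignoring the cross term
overstates the SE several-fold. No cluster-robust correction is applied by
default, matching the lobe-independence assumption.

The proportional-hazards check is the global scaled-Schoenfeld test with the
Kaplan–Meier time transform (transform configurable). Kaplan–Meier
injury-free survival is computed at the **patient** level (a patient fails at
the earlier injured lobe) with Greenwood confidence limits, reporting 36- and
60-month rates.

## Logistic route (`logistic`)

Eligibility: every injured lobe is kept (an injury observed before a later
censoring event is a real response — a strict-exclusion toggle drops such
patients entirely); uninjured lobes count as "normal" only when follow-up
exceeds the window, 50 months by default (the window within which nearly all
injuries manifest). The fit is maximum likelihood via IRLS (statsmodels),
covariance from the inverse observed information; complete or
quasi-separation is detected and raised, never silently diverged.
`TD_p = (logit(p) − b₀)/b₁` with delta-method SE from gradient
`(−1/b₁, −TD_p/b₁)`. Dose-response curves carry **horizontal**
(dose-direction) ±1 SE bands: each probability level's TD shifted by its SE
— the natural rendering when the error is quoted on the dose axis; vertical
probability bands can be derived from the same covariance. Crude incidences
are binned in half-open `[k·w, (k+1)·w)` intervals (w = 2.5 Gy, origin 0),
rates per lobe, empty bins omitted.

Two systematic effects matter when comparing this route to the generative
truth. First, the generative response is complementary-log-log in dose, so a
logistic fit extrapolated far outside the observed dose support acquires a
link-mismatch bias. Second, eligible lobes have heterogeneous observation
horizons (50–106 months), so the binary response mixes failure probabilities
at different times. Recovery of the generative TD50 is therefore validated
under a horizon-aligned design — follow-up just past 60 months, no competing
censoring, dose support widened to span the response range — where the
measured bias is a few tenths of a Gy. Under the default study conditions
the logistic TD50 sits a few Gy below the 60-month Cox TD50 (longer average
observation), still within joint uncertainties at the study's sample size.

## Cohort statistics (`stats`)

Crude rate = 100·events/total, one decimal. Categorical comparisons use the
uncorrected Pearson chi-square when every expected count is ≥ 5, otherwise
Fisher's exact (two-sided) — the switch that reproduces the published
baseline-table P values, and an inference about the original software's
behaviour. Continuous comparisons use Welch's t by default (rank-sum
offered). All tests two-sided at α = 0.05; no multiplicity correction.

Note for verification: a label-permutation oracle conditions on both table
margins, so it reproduces Fisher's exact P to Monte-Carlo accuracy, while
the chi-square CDF P differs from it by a discreteness (continuity) term of
order `2φ(z)/σ_a`; the test suite accounts for that term explicitly.

## Pipeline and CLI (`pipeline`, `cli`)

Stages (cohort → screen → Cox → logistic → summary) run in order, each
persisting its artifact before the next starts; failures abort with the
stage name and keep partial artifacts. Reports embed a provenance block
(effective config, its hash, seed, package version); identical config + seed
gives bit-identical outputs. Input modes: simulate, per-lobe cohort CSV, or
a directory of DVH CSVs plus an outcomes table. YAML config; every CLI flag
overrides its config key.

## Problem sizes used in validation

Parameter recovery runs at 2,000–2,500 lobes (single replicates, 3-SE
checks); selection consistency uses 50 replicates of 300 lobes with one
strong predictor among 18 noise columns; type-I calibration uses 200
replicates (PH test) and 100 replicates (null dose effect); TD50 recovery
uses five 2,500-lobe replicates of the horizon-aligned design. These sizes
give stable verdicts on one CPU in minutes.

## Known limitations

- The Weibull proportional-hazards latency model has a late tail that real
  TLI latencies may not have; the 50-month window logic is exact, but its
  downstream estimand depends on the follow-up distribution.
- Cox-route TD standard errors are first-order approximations (labelled so);
  the published-style SEs are the logistic-route maximum-likelihood ones.
- No multivariable NTCP model, no Lyman–Kutcher–Burman volume parameter, no
  competing-risks treatment of death, no fractionation correction — all
  deliberate scope choices matching the analysis being reproduced.
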