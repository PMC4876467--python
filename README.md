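# tli-ntcp

Actuarial normal-tissue complication probability (NTCP) modelling of
radiation-induced temporal-lobe injury (TLI) after intensity-modulated
radiotherapy of nasopharyngeal carcinoma.

Late temporal-lobe injury limits how much dose can be delivered to skull-base
tumours. Estimating tolerance doses from retrospective cohorts raises three
methodological problems that this package addresses as one tested pipeline:

1. **Dose summarisation.** Per-lobe cumulative dose-volume histograms (DVHs)
   are reduced to the 15 standard scalars: lobe volume (TLV), mean and median
   dose, the maximum point dose `D_max`, the hottest-volume doses
   `D_0.1cc … D_20cc`, and the absolute volumes `V_40 … V_75`.
2. **Predictor selection under collinearity.** The hot-spot metrics are so
   strongly rank-correlated that ordinary multivariable regression is
   unstable. Selection uses an elastic-net-penalized Cox model
   (α = 0.5, cyclic coordinate descent, Breslow ties) with 10-fold
   cross-validated partial-likelihood deviance, patient-level folds, and the
   1-SE rule.
3. **Actuarial dose-response.** Crude rates understate risk under censoring,
   so tolerance doses come from a univariate Cox model via the 60-month
   failure function

   `F(t | D) = 1 − exp(−H₀(t)·exp(βD))`,   `TD_p = [ln(−ln(1−p)) − ln H₀(t*)] / β`,

   cross-checked by a two-parameter logistic NTCP model
   `p(D) = 1/(1+exp(−(b₀+b₁D)))` on lobes observed long enough for injury to
   have manifested (50-month eligibility window), with delta-method standard
   errors on every `TD_p = (logit(p) − b₀)/b₁`.

Because no patient-level data are distributed, the package ships a synthetic
bilateral-cohort generator (132 patients / 264 lobes, correlated left-right
doses, proportional-hazards injury model, censoring by death, repeat RT and
administrative follow-up) whose ground truth makes every stage testable.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/03_select_predictors.py --seed 0
python analysis/04_cox_dose_response.py
python analysis/05_logistic_tolerance.py
```

which prints (seed 0):

```
injured patients: 10 (crude rate 7.6%)
generative truth: beta = 0.1607/Gy on d_1cc, TD50(60 m) = 79.6 Gy
selected variables: d_max, d_0.1cc, d_1cc, v_70
d_1cc: beta = 0.2423 +- 0.0645 /Gy (z = 3.76, P = 0.00017); PH global chi2 = 0.01, P = 0.92
  F(60 m) = 5% at 66.2 +- 1.7 Gy
  F(60 m) = 50% at 76.9 +- 2.7 Gy
Kaplan-Meier injury-free: 98.1% at 3 y, 91.2% at 5 y
d_1cc: TD10 = 67.0 +- 1.4 Gy ... TD50 = 75.7 +- 2.9 Gy   (logistic, n = 144 eligible lobes)
```

The elastic net picks the hot-spot cluster (`d_max`, `d_0.1cc`, `d_1cc`,
`v_70`) out of 19 candidates; the Cox 60-month failure function puts the 5%
tolerance dose for `D_1cc` near 66 Gy on this draw (generative value 63.4 Gy,
within the quoted uncertainty); and the logistic route gives consistent TDs
with maximum-likelihood errors. `analysis/02_dose_metrics_summary.py` and
`analysis/06_cohort_table.py` produce the per-variable dose summaries and the
baseline comparison table; `analysis/07_anchor_td_tables.py` rebuilds full
tolerance-dose tables from published two-anchor calibrations.

The same stages are scriptable through a CLI:

```bash
tli-ntcp run-all --seed 0 --outdir results
tli-ntcp simulate / select / cox / logistic / report   # individual stages
```

Every run writes its artifacts (CSV tables, JSON reports, a provenance block
with config hash and seed) into `--outdir`; identical config + seed gives
bit-identical reports.

## Layout

- `src/tli_ntcp/` — library: `dvh`, `simulate`, `coxnet`, `coxmodel`,
  `logistic`, `stats`, `records`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — models, assumptions, calibration and numerical choices.
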