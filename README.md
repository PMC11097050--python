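# precohort

Precision-cohort treatment-options analytics for longitudinal primary-care
EHRs, with type 2 diabetes mellitus (T2DM) as the built-in use case.

When a patient presents with an uncontrolled disease measurement, the
clinician faces a treatment decision. `precohort` mines a longitudinal EHR
database for comparable historical *decision points* (DPs), ranks them by a
learned disease-specific similarity metric, and reports what happened to the
most similar patients under each treatment option — turning routine records
into decision support.

## The workflow

1. **Ingest** five event tables: patient registry, prescriptions (ATC),
   consultations (CTG), clinical measurements (NHG), and comorbidity
   episodes (ICPC, with 4/8/16-week, long-lasting or chronic duration).
2. **Decision points.** A DP is a test with HbA1c > 7 % or fasting glucose
   > 7 mmol/L after diagnosis that has a follow-up test of the same variable
   90–365 days later; the follow-up value labels the outcome *controlled*
   (≤ threshold) or *uncontrolled*. Each DP carries the active treatment
   regimen, the new regimen taken in the observation period ("no change" if
   identical), guideline flags (age > 70 y, disease duration > 10 y,
   BMI < 25 kg/m²), mobility/mental impairment flags, and a baseline
   clinical snapshot.
3. **Patient similarity.** Features pass a completeness filter (≥ 80 %
   observed), 2-nearest-neighbor imputation, an outcome-stratified 30/70
   train/score split, and LASSO stability selection (features with nonzero
   coefficients in ≥ 150 of 200 L1-logistic fits on 75 % subsamples). A
   large-margin nearest-neighbor criterion then learns nonnegative
   per-feature weights W of the distance

   d(x_i, x_j) = √( Σ_f W_f · (x_{i,f} − x_{j,f})² ),

   a Mahalanobis-type metric with the inverse covariance replaced by the
   learned diagonal W.
4. **Precision cohorts.** DPs sharing the query's *filter key* (true
   guideline/impairment flags + active treatment, e.g.
   `age_above_70y+metformin`) form a filter cohort; only cohorts with
   > 200 DPs are eligible. Members are ranked by distance to the query,
   normalized as (d − d_min)/SD(d), and retained below a cutoff of 2.
   Covariate balance between the treatment-change and no-change groups is
   the standardized mean difference (treated-group SD denominator).
5. **Outcomes analysis.** Per treatment option (e.g.
   `Healthy lifestyle_metformin_new+metformin_stop`): DP count, percent
   controlled, difference versus "No change", and a 2×2 χ² test against the
   baseline at a Bonferroni-corrected 0.05 level. Options under 1 % of the
   cohort (minimum 10 DPs) are excluded from testing. Results export as
   tables and Sankey-diagram data.

Because clinical EHR databases are access-restricted, the package ships a
synthetic five-table EHR generator with known ground truth (per-treatment
control probabilities, guideline covariates, comorbidities, missingness,
confounding), so the full workflow is testable end to end.

## Worked example

```bash
precohort run-all --simulate --n-patients 2000 --seed 7 --out demo/
```

prints (abridged):

```
hba1c: 12092 DPs, 4 stable features, F1 raw/transformed = 0.492/0.494
glucose: 14606 DPs, 33 stable features, F1 raw/transformed = 0.299/0.298
```

and writes `demo/global_options_hba1c.csv`, whose top rows are:

| option | n | pct_controlled | delta | significant |
|---|---|---|---|---|
| No change | 5919 | 46.70 | — | — |
| Gliclazide_healthy lifestyle_metformin_new+healthy lifestyle_metformin_stop | 623 | 50.24 | +3.54 | no |
| Healthy lifestyle_metformin_new+metformin_stop | 335 | 65.37 | +18.67 | **yes** |

Read: among simulated patients on metformin whose HbA1c was uncontrolled,
adding lifestyle advice to metformin was followed by a controlled HbA1c in
65 % of decision points versus 47 % under "no change" — an 18-point,
Bonferroni-significant difference (this is the generator's built-in effect,
recovered by the pipeline). Other artifacts: per-DP CSVs, the similarity
model JSON (feature weights), filter-cohort size charts, Sankey JSON, and a
JSON-lines run log with per-stage counts and timings.

The same stages are available individually (`simulate`, `ingest`,
`extract-dps`, `select-features`, `train-similarity`, `build-cohort`,
`analyze`) and as library functions.

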