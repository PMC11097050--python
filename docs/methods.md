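# Methods

## Scope and data model

The package implements a retrospective decision-support workflow over five
longitudinal primary-care tables (registry, prescriptions, consultations,
clinical measurements, comorbidity episodes), specialized to type 2
diabetes: decision-point (DP) extraction, similarity-metric learning,
precision-cohort construction, and treatment-option outcome statistics.
Clinical codes (NHG, ATC, ICPC, CTG) are mapped to descriptions from small
bundled dictionaries covering the diabetes medications, the glycemia/BMI/
blood-pressure/lipid measurements, the lifestyle-advice records, and the
mobility and mental-state comorbidity sets; unmapped codes pass through
with the raw code as description.

## Decision points

A DP is an index test (HbA1c > 7 % or fasting glucose > 7 mmol/L, strictly
greater) dated after the diagnosis date, paired with the **earliest**
same-variable test 90–365 days later; that follow-up test's value labels
the outcome (*controlled* iff ≤ threshold). A patient contributes as many
DPs as qualify, and a follow-up test may itself be the next index. Choices
the data model leaves open, fixed here:

* several same-day tests collapse to their maximum for index/outcome
  decisions and to their mean for baseline features (deterministic, and
  conservative for "uncontrolled" qualification);
* equality with the threshold counts as controlled (a total rule is
  required; the strict inequalities of the definitions leave 7.0 undefined);
* a medication is *active* at a date if its most recent prescription lies
  within 180 days before it (configurable); prescriptions carry no duration
  or dose, and dose changes are therefore invisible ("no change");
* lifestyle advice has no end date and persists once given; the three
  registered advice forms (dietary advice, healthy-food advice,
  physical-activity advice) collapse into one "healthy lifestyle" component;
* the *new* regimen of a DP is read from the observation period:
  medications prescribed after the index date up to the outcome date, plus
  lifestyle status at the outcome date;
* a missing BMI yields `bmi_below_25 = False` (filter variables must be
  total; absence of evidence is treated as flag-off);
* mobility/mental impairment is active for chronic episodes from their
  start onward and for temporary episodes only within [start, end], with a
  missing end imputed from the 4/8/16-week episode class; the five episode
  duration classes collapse to temporary (4/8/16 weeks) versus chronic
  (long-lasting, chronic);
* disease duration is measured from the registry diagnosis date; with
  diagnoses in 2012–2014 and five-year follow-up the > 10-year flag is
  structurally false on simulated data but kept for generality.

## Feature pipeline

Features per DP: index value, most recent baseline value of each clinical
measurement, the five guideline/impairment flags, `has_chronic_comorbidity`,
four history counts (prescriptions, measurements, consultations,
comorbidities from diagnosis to index), and one-hot encodings of the active
and new treatment labels. Processing order: completeness filter (keep
columns ≥ 80 % observed) → k-nearest-neighbor imputation (k = 2, uniform
weights, Euclidean over mutually observed features) → outcome-stratified
split (|train| = ⌊0.30·n⌋) → standardization of continuous columns (mean/SD
fit on the training set; binary columns untouched). Imputation precedes the
split, mirroring the source workflow; scaling parameters are learned on the
training set only.

**Stability selection.** 200 L1-regularized logistic models on independent
75 % row subsamples; a feature is stable if its coefficient is nonzero in
≥ 150 models. The penalty grid (100, 20, 10, 2, 1.67, 1.43, 1.25, 1.11, 1)
is read as inverse penalties on the mean-log-loss scale (λ = 1/α, the
glmnet/Lasso convention), converted to scikit-learn's sum-loss `C` as α/n;
larger α is a weaker penalty, and the grid spans the path from near-OLS to
all-coefficients-zero. The working α is chosen by 5-fold cross-validated F1
(positive class = controlled, 0.5 threshold) with the **one-standard-error
rule**: the strongest penalty whose mean F1 is within one SE of the best.
A bare argmax is noise-driven across the flat weak-penalty region and
admits uninformative features; the 1-SE rule is the standard LASSO
convention and keeps selection sparse.

The one-hot columns of the *new* treatment are excluded from the similarity
feature set: the new treatment is the decision under evaluation, and the
cohort around a query must not be shaped by it.

## Similarity metric

The patient distance is d(x_i, x_j) = √(Σ_f W_f (x_{i,f} − x_{j,f})²) with
nonnegative per-feature weights — a Mahalanobis-type distance whose inverse
covariance is replaced by a learned diagonal W. W is fit with the
large-margin nearest-neighbor (LMNN) objective: (1 − μ) times the summed
squared distances to each point's k same-class target neighbors, plus μ
times the hinge-penalized margin violations [1 + d²(i, target) −
d²(i, impostor)]₊, with μ = 0.5. Restricted to diagonal weights both terms
are linear in W, so the objective is convex piecewise-linear; it is
minimized by projected subgradient descent (start at the Euclidean metric,
adaptive step size, 200-iteration cap, relative-change tolerance 1e-5 with
3-step patience). Weights are normalized to mean one — the overall scale of
a metric is arbitrary. k is selected from {2,…,7} by 5-fold CV on the
training set, scoring a 5-NN classifier on the transformed held-out fold;
training populations beyond `max_rows` (default 1200; 800 in the pipeline)
are subsampled before metric learning to bound the O(n²) pairwise work.

The metric's benefit is quantified by a KNN grid search (neighbors 3–30,
uniform/distance weights) selected by CV on the training set scoring raw
and transformed representations jointly, then evaluated once on the scoring
set for both; model selection never touches the scoring set.

**Known property of the margin objective.** With a *single* noise feature,
the true minimizer of the diagonal LMNN objective can place more weight on
the noise axis than on a discriminative axis: overlapping-tail impostor
pairs are inseparable along the signal and the only way to buy margin is to
inflate the noise coordinate. With realistic dimensionality (several noise
features, standardized inputs — the regime of the pipeline's feature
matrices), the informative feature is consistently upweighted relative to
every noise feature. The recovery tests therefore use the multi-feature
separable setting.

## Precision cohorts and covariate balance

Filter key: sorted true guideline/impairment flags plus the active
treatment, joined with "+"; all-false with no treatment renders as
`all_guidelines_variables_false`. Cohorts of ≤ 200 DPs are retained for
reporting but ineligible for precision cohorts (a structured "insufficient
data" result, not an error).

Distances from the query to cohort members are normalized as
(d − d_min)/SD(d) — zero for the closest member, and the default cutoff 2
reads "within two spreads of the closest match"; members strictly below the
cutoff form the precision cohort. A plain min–max map to [0, 1] would make
a cutoff of 2 unreachable; this min-anchored, spread-scaled form is the
interpretation adopted and is configurable. The query's own DP is excluded
from the members: with it included d_min is identically zero and the
normalization degenerates, and a patient's own outcome is not evidence
about their alternatives.

Covariate balance is the standardized mean difference: (mean in the
treatment-change group − mean in the no-change group) / sample SD of the
change group, summarized as the maximum absolute value over the similarity
features. When balance is tracked across nested subsets (the
balance-versus-distance profile, 20 equal-width bins), the denominator is
held fixed at the full cohort's change-group SD, the standard convention
when comparing SMDs before and after matching — a shrinking within-subset
SD would otherwise inflate the ratio mechanically. Covariates whose
change-group SD is below a relative epsilon are skipped with a warning.

## Outcomes analysis

DPs group by transition label (`NEW_new+OLD_stop`, baseline `No change`).
Per option: count, percent controlled (half-up rounding to two decimals),
difference versus baseline in percentage points, and a 2×2 χ² test
(controlled/uncontrolled versus the baseline group, no continuity
correction, margins-based expected counts). Options with fewer than
max(10, ⌈0.01·total⌉) DPs are reported but excluded from testing; the
Bonferroni family is the included non-baseline options of one analysis, and
the significance level is 0.05. Sankey export: one link per included
option (width = DP count) splitting into controlled/uncontrolled terminal
nodes; option color green/red by sign of the difference versus baseline,
dark shades iff significant, gray for the baseline.

## Synthetic EHR generator

The generator emulates a primary-care T2DM extract: patients diagnosed
2012–2014 with six months of prior history (pre-diagnosis consultations and
glycemia tests) and five years of follow-up; HbA1c on the percent scale
(values 5.6–11), fasting glucose in mmol/L (4.5–15); yearly BMI, blood
pressure and LDL measurements with configurable per-feature missingness;
lifestyle advice as measurement records with the three registered
descriptions; mobility/mental comorbidity episodes with realistic duration
classes; repeat prescriptions every 90 days while a medication is active.

The closed loop with the extractor: treatment changes are placed 3–25 days
after uncontrolled HbA1c tests, and the outcome of each decision is
attached to the next HbA1c test, whose spacing (≈ 95–350 days at the
default rate of 2.5 tests/patient-year) guarantees it is the earliest test
in the 90–365-day window. The follow-up test is controlled with probability
`control_prob[new regimen]` (default: "no change" 0.45, metformin 0.55,
healthy lifestyle 0.52, healthy lifestyle + metformin 0.62, gliclazide +
metformin 0.50), shifted on the logit scale by `confounder_strength` times
a patient-level confounder score (0.6·latent severity + 0.5·standardized
age + 0.4·standardized BMI). The same score shifts the probability of
changing treatment and the preference for lifestyle advice, so treatment
choice and outcome are confounded through measured covariates, as in real
EHR data; `confounder_strength = 0` recovers exact per-option control
probabilities. Ages and BMI are drawn so that age > 70 and BMI < 25 each
hold for ≈ 25 % of patients. The fasting-glucose test stream is passive
(severity-correlated values; it does not trigger treatment changes),
mirroring the primary role of HbA1c in medication-change decisions.

What the generator does **not** emulate: dose changes, inter-practice
variation, realistic coding-system coverage, free-text records, calendar
seasonality, and mortality/dropout. Passing tests therefore demonstrate the
pipeline's correctness and statistical behavior on data with known truth,
not clinical validity on real records.

## Test and experiment sizes

Unit fixtures are hand-enumerable toy patients. The statistical suites use:
parameter recovery, 20 seeds × 3,000 patients (no confounding; recovery of
45 %/65 % within 3 points and Bonferroni-significant detection of the
+20-point option); familywise error, 500 replicates of direct per-option
binomial outcome tables under a shared null (the natural unit for a FWER
property of the testing procedure); stability-selection recovery, 10 seeds
× 400 rows × 21 features; metric benefit, separable sets of 600 rows;
balance behavior, one 2,000-patient population at `confounder_strength = 2`
with 50 random queries — the balance-improvement property is only
measurable when baseline confounding dominates the sampling noise of a
max-|SMD| summary at precision-cohort sizes, and strength 2 produces
unfiltered imbalance ≈ 0.5, typical of unadjusted clinical treatment
comparisons.

## Known limitations

* The LMNN weight extraction assumes a diagonal metric; feature
  interactions (a full transform) are not modeled.
* The balance summary is a maximum over ~20–30 covariates and is noise-
  inflated in small precision cohorts; the fixed-denominator convention
  mitigates but does not remove this.
* The χ² comparisons are association statistics over observed decisions,
  not causal effect estimates; no propensity weighting or outcome modeling
  is applied beyond the cohort filtering itself.
* The 1-SE rule, the 180-day active-medication window, the lifestyle
  persistence assumption and the min-anchored distance normalization are
  documented defaults, all configurable.
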