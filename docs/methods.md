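# Methods

## Cohort model

The unit of input is a visit-level claims record: subject id, sex, birth
date, visit date, visit type (outpatient / emergency / inpatient) and one
ICD-9-CM diagnosis code.  A **case** of the target disease (default prefix
`428`, heart failure) is a subject with at least one target-code record of
a qualifying visit type — emergency or inpatient by default, because
outpatient target codes are considered too unreliable for case
ascertainment; the index date is the first such visit.  A subject whose
only target-code records are outpatient is neither case nor control.  A
**control** has no target-code record of any visit type anywhere in their
history.

Controls are drawn without replacement, matched on sex and 5-year age band
(`match_on="age_sex"`), and inherit the index date of a case in their
stratum: the data themselves define no control index date, and inheriting
the matched case's date makes the lead windows calendar-comparable.
Comorbidity codes are collected from **all** visit types — only case
identification is restricted — inside the half-open window
`[index − lead_years, index)`, so the diagnosis day itself is excluded.
Codes are deduplicated per subject (sets, not multisets) after mapping to
the chosen granularity:

* `single` — the 3-character ICD-9-CM category (`4280 → 428`, `V720 → V72`;
  E codes keep four characters), and
* `group` — a block-level range table bundled as package data (148 standard
  ICD-9-CM sub-chapter blocks including V/E ranges), overridable by any
  two-column range CSV.  The granularity experiment needs *a* consistent
  partition; the exact published partition is not available, so the
  standard chapter blocks stand in.

## Association statistics

Per comorbidity code, the case-control 2×2 table (a, b, c, d) yields:

* **odds ratio** `((a+k)(d+k)) / ((b+k)(c+k))` with continuity correction
  `k = 0.5` per cell (Haldane–Anscombe) by default.  `k = 0` reproduces
  textbook worked values on tables with no empty cells; `k = 0.5` is the
  pipeline default because zero cells are routine in sparse claims data.
* **alpha index** `ln[(P₁/(1−P₁))/(P₂/(1−P₂))]` with
  `P₁ = (a+k)/(a+c+2k)`, `P₂ = (b+k)/(b+d+2k)` — algebraically identical
  to `ln(OR)` at equal correction (property-tested to 1e-12).  The same
  correction is used for the OR and α of a feature for internal
  consistency.
* **prevalence** `a/(a+c)` and `b/(b+d)`, with a pseudo-count (default 1)
  substituted **only** when the numerator is zero, so never-observed codes
  keep a non-null proportion.

The **feature set** keeps every code observed among cases with
`OR ≥ or_min` (default 2) and case prevalence `≥ prevalence_min` (default
0.01), sorted by descending OR.  Weights for the weighted indices are
z-scores of the selected members' own OR (resp. α) distribution —
population SD, no clipping; a strict mode can clip to [−1, 1] — mapped
through a T-transform `z·√n / C`, `n` the cohort size and `C` the
two-sided 97.5% t critical value at `n−1` df.  The printed form of this
transform in the source literature is typographically ambiguous; since the
weighted indices are invariant to positive rescaling of the weights, the
choice affects only which weights fall below zero.  The conventional
educational T-score (50 + 10z) is available as `tscore_style=
"classic_50_plus_10z"`.  If only one feature survives selection (or all
ORs tie) the z-scores are degenerate; the selector then assigns z = 0 to
all members with a warning rather than failing.

## Similarity indices

`jaccard`, `pji` and `weighted_pji` implement the three index families over
normalised profiles (see README for the formulas).  Design points:

* Empty-vs-empty comparisons are defined as 0, not NaN.
* T-score weights are negative below the weight mean, which would break the
  mass interpretation of a Jaccard-style ratio; weights are floored at
  ε = 1e-6 (a shift-free floor that preserves the ranking of positive
  weights) and the floored indices are provably in [0, 1].
* A subject is featurised as a **uniform**-proportion profile over their
  feature-set comorbidities and compared against the case-group and
  control-group carriage-proportion profiles, giving two features per
  index.  Two reference similarities (rather than one) make the classifier
  well-posed for any model family; visit counts are deliberately not used
  as subject proportions, since per-subject visit counts measure
  utilization more than morbidity.
* `featurize_cohort` is vectorised (membership matrix × profile vectors);
  tests cross-check it row-by-row against the scalar index functions.

## Prediction pipeline

Outer loop: stratified K-fold with `K = round(ln n)` by default
(n = 17,000 → K = 10), shuffled, seeded; a warning is raised when
`n/K ≤ 3d`.  Within each outer-training fold the majority class is
subsampled to 1:1 before fitting; the untouched outer test fold is scored.
Inner loop: 3-fold grid search (accuracy) over small standard grids — LR:
C over 5 log-spaced values; SVC: RBF, 5 C values; RF: 100/300 trees ×
depth ∅/8; XGB: depth 3/6 × learning rate 0.1/0.3.  The reported
`model_score` is the selected inner model's validation accuracy; other
metrics (precision, sensitivity, specificity, accuracy, F1, AUC) come from
the held-out outer folds, and the report's headline metrics are their
arithmetic means.

Leakage control is structural: `run_experiment_grid` hands `nested_cv_train`
a *featurizer callback* that re-selects the feature set and rebuilds the
case/control reference profiles from the outer-training subjects of each
fold, so held-out subjects cannot influence feature selection (tested by
planting a marker code exclusively in held-out subjects).  The full
configuration grid enumerates 2 code levels × 3 lead times × 4 indices ×
4 model families × 5 subgroups (all, age <65, age ≥65, female, male) =
480 cells; seeds fan out per cell via a CRC of the cell tag, so results
are independent of cell evaluation order.

## Synthetic claims generator

The generator emulates the *shape* of a national claims extract, not
disease biology.  Defaults: 8500 cases / 21786 controls (≈1:2.56), male
share 0.493, age ~ N(58, 16²) truncated to [20, 95], visit mix
70/10/20% outpatient/emergency/inpatient, one common index date, and a
122-category code universe —

* 12 strongly associated categories with planted ORs 2–12 at control
  prevalences 0.01–0.12 (rare-strong / common-moderate geometry typical of
  published comorbidity tables),
* 30 mildly associated categories with ORs 1.3–2.4 straddling the
  selection threshold, and
* 80 null categories (OR 1) across a prevalence ladder 0.003–0.15.

Case carriage probabilities invert the odds relation
`p_case = OR·odds_ctrl / (1 + OR·odds_ctrl)`, so the planted OR is the
exact expectation.  Two structural features of real claims data are
modelled: **utilization heterogeneity** — a lognormal subject-level factor
(SD 1.0, median 1, identically distributed in both groups) multiplies every
carriage odds, producing the overdispersed per-subject code burdens seen in
practice while leaving null codes null — and optional **block correlation**
(`block_correlation` ∈ [0,1)) via a shared Bernoulli factor per ICD block
that preserves marginal prevalences.  The utilization effect attenuates
realized marginal ORs relative to planted values (ordinary
non-collapsibility), which the recovery tests account for by checking
rank/log-scale correlation rather than exact equality.

Not modelled: disease progression and temporal ordering within the window,
code co-occurrence beyond block level, sex/age-dependent prevalences, and
coding error.  Consequently, passing tests demonstrate that the estimators
and the pipeline recover *planted* association structure from
realistically shaped tables — they do not validate clinical performance on
real claims data.

## Problem sizes and numerical choices

Tests run at desk scale: the shared simulated cohort is 800/2000; the
fixed-seed recovery study follows the stated design of 5000 cases / 12500
controls (built with `match_on="none"` so the cohort size is exact; age/sex
matching is exercised separately with a surplus control pool, because a
pool at exactly the requested ratio cannot be matched per-stratum without
shortfall).  Model-comparison checks use logistic regression, the cheapest
family, with the default fold rule.  Degenerate inputs are defined rather
than fatal wherever a convention exists (empty profiles → similarity 0;
all-equal scores → AUC 0.5 with a warning; zero-cell tables → explicit
error advising a positive correction).  Code iteration order is fixed by
sorted code string throughout, and every stochastic step takes an explicit
seed, so all pipeline outputs are reproducible bit-for-bit.
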