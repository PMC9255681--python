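# Methods

`fallrisk` implements the development and internal validation of a one-year
fall-risk prediction model for community-dwelling adults aged 65+ from
primary-care EHR extracts: rule-based ascertainment of falls from free-text
consultation notes, engineering of 79 candidate predictors from coded
medication/diagnosis tables, death-weighted logistic regression with
bootstrap-enhanced lasso (Bolasso) variable selection, and 10-fold nested
cross-validation of the entire strategy. Because the registry this class of
study draws on is not public, the package ships a synthetic cohort generator
whose outcome process follows the published final model, giving every
downstream stage a gold standard to be tested against.

## Study design emulated

A fixed index date (default 2018-12-31) splits each patient's record into a
12-month *observation* window `[index − 365 d, index)` supplying predictors
and a 12-month *follow-up* window `[index, index + 365 d)` supplying the
outcome. All windows are half-open ISO intervals. Eligibility is age ≥ 65 at
observation start.

## Synthetic cohort generator

The generator inverts the final model: each patient receives a predictor
vector `x` (age plus 78 independent Bernoulli indicators at configurable
marginal prevalences) and falls with probability
`sigmoid(β₀ + βᵀx)`. Defaults are the published values:

- **Coefficients.** Intercept −6.92; age 0.06/yr; female sex 0.26; history of
  falls 0.72; proton pump inhibitors 0.29; opioids 0.24; previous injury
  0.35; depression 0.54; osteoarthritis 0.20; urinary incontinence 0.36;
  memory/concentration problems 0.41. The remaining 69 candidates (31 drug
  groups, 38 condition groups) are null.
- **Prevalences.** The published overall cohort rates wherever the baseline
  table prints them (e.g. history of falls 4 751/36 470 ≈ 13.0 %, PPI ≈
  40.0 %); plausible primary-care rates in [0.02, 0.4] for the example groups
  the source tables do not cover.
- **Age.** 65 + Gamma(shape 2.0, scale 4.2) years, chosen so the cohort
  median age is ≈ 72; under these defaults the implied fall prevalence is
  ≈ 13.3 %, matching the published 13.1 % within Monte-Carlo noise.
- **Deaths** at annual rate 771/36 470 with a uniform date strictly inside
  follow-up; a faller–decedent falls before death. **Consultation gaps**
  (3.8 % of patients have no follow-up note, so their falls are
  unascertainable) and **look-back patients** (2.4 % have their diagnosis
  records only in prior years) are drawn independently.
- **Records.** Every active indicator emits a dated, coded record (7-character
  ATC code from the group's prefixes; ICPC code from the group's list); every
  true fall of a consulting patient and every positive fall history emits a
  trigger-bearing note from a template pool; distractor notes (negated,
  traffic-accident, homonym mentions) are added per patient at configurable
  rates, plus Poisson-distributed unrelated notes. Every note carries a gold
  label from {fall, negated, traffic, homonym, unrelated}.

All randomness flows from one integer seed through fixed per-stage
`SeedSequence` streams, so each stage is independently reproducible and a
fixed seed fixes every output byte.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: predictor correlations (independence by default; a
correlated cohort can be produced by supplying a custom predictor spec but no
published correlation structure exists to calibrate one), realistic clinical
prose (notes are template sentences), multi-year longitudinal structure,
care-process events, and laboratory measurements (excluded from the modelled
predictor set). Parameter-recovery results on this cohort therefore validate
the *procedure*, not its behaviour under real-world collinearity.

## Fall ascertainment from text

A note documents a fall iff some trigger-term occurrence (word-boundary,
case-insensitive, inflection variants enumerated in the lexicon) survives
three filters: no negation cue within the five tokens preceding the trigger
in the same sentence (sentences split on `.!?` and newlines; five tokens is a
common clinical-NLP negation scope), no traffic term in the sentence (traffic
accidents fall outside the clinical definition), and no homonym term in the
sentence (non-falling senses such as the season). When every occurrence is
filtered the first occurrence's reason is reported, giving auditable reason
codes. The outcome is 1 iff a fall-positive note is dated in follow-up;
history of falls applies the same rule to the observation window. The
bundled lexicon is English (a Dutch analogue ships alongside for format
documentation); both are YAML lists a user can replace.

Known limitation, regression-tested directionally: a genuine fall narrated in
the same sentence as a homonym/traffic term is suppressed, so detector
sensitivity degrades as such contexts become more frequent.

## Predictor engineering

33 FRID (fall-risk-increasing drug) groups are prefix matches on ATC codes
dispensed in the observation window; 43 chronic-condition groups are prefix
matches on ICPC codes. Patients without any in-window diagnosis record have
condition indicators filled from prior years (unbounded look-back by
default) and are flagged `lookback_used`. The bundled mappings carry the
published group counts (33/43) and documented file format; they are
illustrative stand-ins for the original supplementary tables, which can be
substituted verbatim. Observation weights: 1 for survivors and for decedents
with an ascertained fall; `days(follow-up start → death)/365` for decedents
without one. The design matrix is `[age, female_sex, history_of_falls, 33
FRID, 43 conditions]` = 79 columns, no missing cells.

## Penalised estimation and Bolasso

The development estimator minimises
`−(1/W) Σ wᵢ ℓᵢ(β₀, β) + λ‖β‖₁` (W = Σwᵢ, intercept unpenalised) over a
30-point geometric λ grid from λ_max (KKT bound at the intercept-only fit)
down to λ_max·10⁻³. The solver is the standard glmnet algorithm — IRLS with
cyclic coordinate descent, warm starts along the path, active-set iteration —
written in-package and numba-compiled, with two-valued columns visited in
O(nnz) through nonzero index lists and a scalar residual shift (the design is
binary except age). It matches R glmnet to ≈1e-7 across a path and the
unpenalised fit at λ→0 to 1e-6 (both tested). Working weights are floored at
1e-5 and the working linear predictor clipped to ±30 for stability.

Per-sample λ is chosen by inner 10-fold cross-validation on weighted
deviance, default `cv_min` with a `cv_1se` switch. The inner folds split the
bootstrap sample directly — the convention of the standard per-sample
cross-validated lasso. This is worth dwelling on, because bootstrap samples
contain duplicated rows, and copies of one row can straddle a
train/validation split; the resulting leakage biases λ towards zero and
roughly doubles the per-sample active sets. A `group_cv` switch assigns
inner folds by original row index, removing the leakage. It is off by
default deliberately: the selection behaviour of the consistency thresholds
(a parsimonious ~10-variable intersection at π = 1.0, roughly twice that at
π = 0.8) was established under plain per-sample CV, and both variants are
exposed so the sensitivity of the selected set to this choice can be
measured. With `group_cv` the chosen λ grows, per-sample active sets
shrink to ~20–45 columns, and the π = 1.0 intersection becomes slightly more
conservative (occasionally dropping the weakest true predictor on synthetic
cohorts); with plain CV the intersection occasionally admits one null whose
realised association in the particular cohort is large.

Bolasso draws `b = 100` bootstrap samples of size n with replacement (rows
carry their weights), fits the cross-validated lasso on each, and records
active sets. Selection at consistency threshold π keeps columns selected in
≥ π·b samples (π = 1.0 primary, 0.8 comparison; the π=1.0 set is a subset of
the π=0.8 set by construction). A non-convergent replicate is redrawn once,
then counted as selecting nothing, with a warning. Selected columns are
refit by unregularised weighted logistic regression (statsmodels GLM with
variance weights); Wald 95 % CIs come from the information matrix;
separation is flagged (`converged=False`, point estimates from a negligibly
ridge-penalised fallback) rather than silently reported.

## Internal validation

`crossvalidate` repeats the whole strategy — Bolasso selection then refit —
on each of k = 10 training folds (stratified on the outcome by default, since
event-free folds are otherwise possible at 13 % prevalence; a non-stratified
switch exists) and scores the held-out fold: weighted ROCAUC (concordance
with ties at ½), weighted average-precision PRAUC (step interpolation, which
avoids the optimism of trapezoidal interpolation), weighted Brier score, and
sensitivity/specificity/PPV at each fold's own Youden-index threshold
(smallest maximiser over observed probability values on ties). Metrics are
summarised as median and IQR over folds, invariantly to fold order.
Calibration uses pooled out-of-fold predictions: equal-count decile bins
(weighted means; fewer bins with a warning under heavy ties) and a
loess-style smooth (tricube-weighted local quadratic regression, span 0.75,
100-point grid; implemented in-package because the available lowess routine
is local-linear only). `permute_test_y` permutes each held-out fold's
outcomes before scoring — a leakage diagnostic whose median ROCAUC must sit
at 0.5. Sensitivity variants re-run the whole procedure after excluding
look-back patients (Model 1) or patients without a follow-up consultation
(Model 2).

## Numerical and design choices

- λ grid 30 points, ratio 10⁻³; CV fits at coefficient tolerance 1e-4, final
  fits 1e-6 (standardised scale). Columns standardised to unit variance
  inside the penalised fit only; coefficients are reported on the original
  scale.
- Ties in λ selection resolve to the larger λ (first index on the decreasing
  grid) under `cv_1se`; `cv_min` takes the arg-min.
- Zero-variance columns (globally or within a bootstrap sample) are never
  active.
- Degenerate inputs: single-class outcomes raise for fits and Youden, return
  NaN for AUCs; an empty selected set yields an intercept-only
  (event-rate) prediction in cross-validation.
- Weight denominator is the configured 365-day follow-up, not 366.

## Problem sizes used in the shipped checks

The test suite exercises cohorts of 500–36 470 patients. Coefficient
recovery and Bolasso selection are checked at the published cohort size
n = 36 470 (selection with 50 bootstrap samples in the suite; the
`scripts/acceptance.py` reproduction uses the full b = 100). Nested
cross-validation sanity runs at n = 10 000 with k = 10 and 8 bootstrap
samples per fold; the bundled demo config uses n = 5 000, b = 25 with a
trimmed inner CV. These sizes were chosen so each check isolates one claim
at the smallest scale with adequate statistical power.

## Known limitations

- Independence of synthetic predictors makes variable selection easier than
  on collinear real data; the π = 1.0 intersection over 100 bootstrap
  samples is intrinsically knife-edged for any predictor or null whose
  per-sample selection probability approaches 1.
- The detector has no scope parser; negation is a token window, not a
  grammatical analysis.
- The bundled code mappings and lexicon are format-faithful examples, not
  the original supplementary tables.
- External validation, decision-curve analysis, recalibration with a
  comorbidity count, laboratory imputation and gradient-boosting variants
  are out of scope.
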