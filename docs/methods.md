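# Methods

This note documents the models, assumptions, parameter choices and known
limitations of `icuq`. Everything quantitative stated here is computed by
the test suite or the pipeline itself.

## Unit of analysis and cohort selection

The unit of analysis is the **ICU stay**, not the patient: one patient may
contribute several stays, and by design nothing about a patient's history
informs a stay's prediction. Cohort preparation mirrors a standard
first-day extraction:

* stays shorter than 1 day are discarded; `los_days = 1.0` exactly is kept;
* every observation series is truncated to the half-open window
  `[0, 24)` hours from ICU admission (half-open to avoid double counting
  the boundary hour);
* ages above 90 years are capped at 90 (the usual de-identification dummy
  for ages > 89);
* readings outside per-vital plausibility ranges, non-positive or
  non-finite readings are dropped. The ranges — HR [1, 300] bpm,
  RR [1, 70] /min, SBP [1, 400] mmHg, DBP [1, 300] mmHg, SpO₂ [1, 100] %,
  temperature [25, 45] °C, glucose [1, 2000] mg/dL — are package
  assumptions (configurable via `CleaningRules`), chosen as generous
  physiologic-plausibility bounds rather than published thresholds;
* per-stay vital means with no retained observations, and any missing
  engineered features, are mean-imputed **at the feature-table level**
  (column mean over observed rows). Imputation provably preserves each
  column's mean and never touches observed entries.

Sample SD (n−1) is used throughout; a single-observation SD is reported as
0 with a warning.

## The tail-quantile transform

For each stay × vital with observations `x₁…xₙ`:

1. `fit_normal`: mean `x̄` and sample SD `s` (0 when n = 1);
2. `tail_cutoffs`: `ℓ = F⁻¹(p_low)`, `h = F⁻¹(p_high)` where `F` is the CDF
   of `N(x̄, s²)`; defaults `p_low = 0.25`, `p_high = 0.75`;
3. `extract_tails`: keep `x < ℓ` or `x ≥ h` (strict below, inclusive
   above), order preserved;
4. `modified_stats` and `quantile_percentage`: tail mean, tail sample SD,
   and tail count divided by n.

Interpretation choices that the procedure's informal description leaves
open, fixed here:

* "normalising by the density" is read as fitting `N(x̄, s²)` and taking
  inverse-CDF cutoffs from the fit — the only reading that makes the
  pipeline well defined;
* tail membership is strict at the low cutoff and inclusive at the high
  cutoff, following the "less than" / "greater than or equal" convention;
* `s = 0` (constant series) collapses both cutoffs onto the mean, so by
  the inclusive rule *every* observation is a tail observation and the
  quantile percentage is 1. This keeps the transform total — no stay is
  silently dropped;
* an empty tail yields (full-sample mean, 0); a single tail observation
  yields (that value, 0) with a warning (`min_tail_count = 2` for a
  defined sample SD);
* sample SD (not population SD) everywhere, matching the package-wide
  convention.

Under exact normality the expected quantile percentage is
`p_low + (1 − p_high) = 0.5`; on real (non-normal) series it varies, which
is precisely what makes it informative. For symmetric samples the modified
mean converges to the sample mean while the modified SD *exceeds* the
sample SD (for standard-normal tails beyond ±0.6745 the conditional SD is
`√(2(cφ(c) + 1 − Φ(c))/0.5) ≈ 1.363`); both properties are asserted by
Monte-Carlo tests against closed forms computed with independent numeric
oracles (bisection on an integrated CDF; no library inverse-CDF).

## Outcomes

* **Mortality**: the stay's in-hospital death flag (prevalence ≈ 11.9% in
  the emulated population — left imbalanced; no resampling or reweighting).
* **LOS binary**: 0 if `los_days ≤ median`, 1 otherwise, with the median
  always computed from the cohort at hand (never a hard-coded constant);
  ties go to class 0. On tie-free even-sized data this yields an exact
  50/50 split.
* **LOS regression**: days, as a continuous target.

## Experiment harness

* 75/25 train/test split by stay (`n_train = floor(0.75 n)`), unstratified,
  seed-deterministic. Splitting by stay (not patient) is deliberate: the
  patient-overlap question is then addressed explicitly by the sensitivity
  analysis, which removes test stays whose patient appears in training and
  reports the overlap count and percentage.
* 10-fold seeded cross-validation on the training set; fold metric is
  held-out accuracy (threshold 0.5) for classifiers and held-out MAE for
  regressors (the regressor CV metric is a package choice; the original
  protocol leaves it unstated).
* Algorithms and tuned hyperparameters: random forest with
  `max_features = 4` and 500 trees (mortality) / 400 trees (LOS); RBF-SVM
  with `C = 1.60` (mortality) / `C = 0.90` (LOS), probability outputs via
  sigmoid (Platt) calibration on internal folds. LR, LDA, kNN (k = 5), XGB,
  MLR and SVR use ecosystem defaults, pinned in `ModelSpec` and recorded in
  every run manifest.
* Inputs are standardised to train-set mean/SD for LR, LDA, kNN, SVM and
  SVR; trees/boosting and plain linear regression see raw features.
* "LR" is logistic regression (probability outputs are required for
  ROC and calibration).

## Metrics

Accuracy, sensitivity, specificity, NPV, PPV from the 0.5-threshold
confusion matrix, each with a 95% CI. The default CI is the **unclipped
Wald interval** `p ± z√(p(1−p)/n)` — upper bounds above 1 are reported as
computed, matching how such intervals are conventionally printed for
near-perfect specificity; a clipped Wilson interval is available via
`method="wilson"`. Zero-denominator metrics are reported as undefined
(NaN), never as 0.

AUROC uses the Mann–Whitney formulation with ties counting ½ and is
tested against exhaustive positive×negative pair counting; the ROC curve's
trapezoidal area equals it to 1e−10. Calibration is assessed by ten
equal-count probability-ranked bins (mean predicted vs observed rate) plus
a logistic recalibration of outcome on the logit of the clipped
probability: slope ≈ 1 and intercept ≈ 0 indicate honest probabilities.
The recalibration-slope reading of the "sigmoid test" is an
interpretation; it is labelled as such in reports. Constant predictions
make the slope undefined (NaN with a warning).

## Synthetic cohort generator

The generator stands in for the credentialed clinical source; it emulates
the statistical structure the analysis assumes, not the clinical substance.
Per stay:

* latent severity `s ~ N(0,1)`;
* observation of vital `v`: `μ_v + λ_v s + ε`, `ε ~ N(0, σ_v²)`, at a
  jittered hourly grid (24 observations/day — an assumption; the emulated
  source does not state charting frequency);
* **tail excursions**: with per-observation probability
  `clip(p_v · exp(0.6 s), 0, 0.9)` the value is displaced by ±2.5 σ_v
  (random sign); defaults `p_v = 0.04`;
* mortality `~ Bernoulli(logit⁻¹(α + 0.9 s + 6.0 · tail_burden))` where
  `tail_burden` is the stay's realized excursion fraction;
* `los_days = clip(exp(N(ln 2.64 + 0.35 s, 1.026²)), 1, 173.07)`;
* 1% of observations are marked missing; demographics: age N(64.35, 16.87²)
  clipped to [18, 90], 56.56% male, height N(160.66, 11.76²),
  weight N(80.45, 23.47²); 80% of patients contribute one stay, the rest
  1 + Geometric(½) stays with shared demographics.

Population vital moments `(μ_v, σ_v)` default to the emulated cohort's
published descriptive statistics (e.g. heart rate 85.99 (15.59) bpm);
SpO₂, whose population SD is not published, uses an assumed 2.0%.
Severity loadings `λ_v` follow clinical deterioration directions (heart
rate, respiration, temperature, glucose up; blood pressures and SpO₂
down) at roughly 0.3–0.4 population SDs per unit severity.

Calibrated constants, fixed once before the modelling work by Monte-Carlo
at n = 200,000 latent draws: the LOS log-scale parameters solve
median = 2.64 days and unclipped mean ≈ 4.75 days
(`σ_total² = 2 ln(4.75/2.64)`, severity share 0.35); the mortality
intercept (−2.6925) makes the mean inverse-logit equal 11.897% under the
default coefficients. The 1-day clipping floor does not move the median.
A 20,000-stay default cohort reproduces median LOS within ±0.15 days and
prevalence within ±1 percentage point (asserted in the test suite).

**Why severity loads on both level and excursions**: if severity only
shifted levels, the per-stay means in the baseline features would already
capture everything and the engineered tail features could not help. The
excursion channel gives the tail features signal the means miss — the
mechanism the transform is designed to exploit — and the signal-recovery
test confirms the engineered mode's random-forest test AUROC exceeds the
baseline mode's on average over 10 seeded 5,000-stay cohorts, while
zeroing the mortality coefficients pushes every AUROC to the null band.
A note on that null band: each finite cohort realizes a chance
feature–label association shared by its train and test halves, so null
test AUROCs spread several times wider than the Mann–Whitney SE; the test
therefore uses the empirical SD across seeded runs (≈ 0.046) as its
yardstick.

What the generator does **not** emulate: within-day autocorrelation beyond
the excursion mechanism, informative missingness, inter-vital correlation
beyond the shared severity factor, ICU type, diagnoses, labs or
interventions. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that the transform recovers tail-borne signal
*when it exists* — they do not certify performance on real clinical data,
and the published headline accuracies of the emulated study are not
reproduction targets here.

## Problem sizes

Default problem sizes were chosen so the full suite exercises every stage
at meaningful scale: generator calibration at 20,000 stays, signal
recovery at 10 × 5,000 stays, pipeline smoke runs at 50–60 stays with the
complete 28-row grid, and Monte-Carlo oracles at 10⁶ draws.

## Known limitations

* Mean imputation understates variance and ignores missingness mechanisms.
* The Wald CI is degenerate at p ∈ {0, 1} (zero width); use the Wilson
  option when that matters.
* The calibrated SVM's probability quality depends on its internal fold
  count; on very small minority classes the model degrades to a constant
  predictor (with a warning) rather than failing.
* The unclipped-normal default CI and the recalibration-slope calibration
  test are documented interpretations of under-specified conventions, not
  the only defensible ones.
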