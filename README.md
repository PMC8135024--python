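# icuq — ICU mortality and length-of-stay prediction from vital signs

`icuq` is a reproducible pipeline for predicting two intensive-care outcomes —
in-hospital mortality and ICU length of stay (LOS) — from nothing but
first-day vital-sign observations and basic demographics. It is aimed at
clinical-informatics researchers who want to benchmark *minimal-feature*
outcome models: no labs, no diagnoses, no severity scores, just the seven
routinely charted measurements (heart rate, systolic and diastolic blood
pressure, respiration rate, body temperature, SpO₂, glucose) plus age,
gender, height and weight.

## The tail-quantile feature transform

The package's core is a feature-engineering procedure that emphasises the
*extremes* of each stay's vital-sign distribution, on the clinical argument
that deterioration shows up as unusually high or low readings rather than as
a shift of the typical value. For each vital ``v`` within each stay:

1. fit a normal by the stay's sample moments: ``X_v ~ N(x̄_v, s_v²)``;
2. compute inverse-CDF (percent point function) cutoffs
   ``ℓ = F⁻¹(0.25)``, ``h = F⁻¹(0.75)``;
3. keep only the tail observations ``{x : x < ℓ or x ≥ h}``
   (the first and fourth quantiles of the fitted distribution);
4. summarise them as the **modified mean** ``x̄ᵐᵒᵈ_v``, the **modified SD**
   ``sᵐᵒᵈ_v``, and the **quantile percentage**
   ``q_v = #tails / #observations``.

This yields 3 features per vital, 21 per stay, appended to the 12 baseline
predictors (7 per-stay vital means + 5 demographics) to give a 33-predictor
"quantiles" feature mode. Six classifiers (logistic regression, LDA, random
forest, kNN, RBF-SVM, gradient boosting) serve the two binary targets —
mortality, and LOS dichotomised at the cohort's own median — and two
regressors (linear regression, SVR) predict LOS in days. Evaluation covers
accuracy, sensitivity, specificity, NPV and PPV with 95% CIs, AUROC/ROC,
MAE/RMSE, and decile calibration with a logistic recalibration check.

Because the real source data (a credentialed clinical database) cannot be
redistributed, the package ships a synthetic cohort generator that emulates
its statistical structure — population vital-sign moments, a latent severity
score that shifts vital levels, severity-dependent *tail excursions*, a
lognormal LOS (median ≈ 2.64 days) and a logistic mortality model
(prevalence ≈ 11.9%) — so every stage is exercisable end to end with no
data access. See `docs/methods.md` for the generative model and its
calibration.

## Worked example

```python
from icuq import CohortConfig, ICUOutcomeModel, generate_cohort
from icuq.prep import aggregate_baseline, clean_stay, filter_first_day, impute_mean
from icuq.quantiles import QUANTILE_FEATURES, assemble_feature_table, engineer_table
from icuq.synth import VITALS

stays = [clean_stay(s) for s in filter_first_day(generate_cohort(CohortConfig(n_stays=5000, seed=0)))]
baseline = impute_mean(aggregate_baseline(stays), [f"{v}_mean" for v in VITALS])
engineered = impute_mean(engineer_table(stays), list(QUANTILE_FEATURES))
table = assemble_feature_table(baseline, engineered, "quantiles")

res = ICUOutcomeModel(table, target="mortality", mode="quantiles",
                      algorithm="RF", seed=0).fit()
print(res.summary())
```

prints

```
ICU outcome prediction results
==============================================
target:            mortality
feature mode:      quantiles (33 predictors)
algorithm:         RF
split:             75% train, 10-fold CV, seed 0
test stays:        1250
CV accuracy:       0.8875 (SD 0.0145)
----------------------------------------------
accuracy      0.8616  (0.842-0.881)
sensitivity   0.1278  (0.079-0.177)
specificity   0.9850  (0.978-0.992)
npv           0.8704  (0.851-0.889)
ppv           0.5897  (0.435-0.744)
auroc         0.76239
calibration   slope 0.808, intercept -0.192
```

Read: on a 5,000-stay synthetic cohort the tuned random forest (500 trees,
at most 4 features per split) reaches 86.2% test accuracy and an AUROC of
0.762. As with the real cohorts this emulates, accuracy is dominated by the
~88% survivor majority — specificity is near 1 while sensitivity is low —
which is why AUROC and calibration are reported alongside it; the
recalibration slope and intercept quantify how honest the predicted
probabilities are. Swapping `mode="baseline"` (12
predictors) lowers the RF AUROC; the engineered tail features carry signal
the per-stay means miss.

## Command line

```bash
icuq run-all --config config.yaml --out runs/exp1 --seed 0 -v
icuq report --out runs/exp1
```

Subcommands `simulate`, `prepare`, `features`, `outcomes`, `train`,
`evaluate`, `report` and `run-all` each read and write only documented
CSV/JSON artifacts (`stays.csv`, `observations.csv`,
`baseline_features.csv`, `quantile_features.csv`, `outcomes.csv`,
`results.json`, `sensitivity.json`, `manifest.json`), so stages can be run
and audited independently. A full run produces the 28-row result grid
(2 binary targets × 2 feature modes × 6 classifiers + regression × 2 modes
× 2 regressors), a patient-overlap sensitivity analysis and an age-ablation
comparison.

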