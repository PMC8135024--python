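"""Split arithmetic, patient-overlap handling, cross-validation and the
Model/Results front end."""

import numpy as np
import pandas as pd
import pytest

from icuq.models import (
    CLASSIFIERS,
    ICUOutcomeModel,
    ModelSpec,
    SplitSpec,
    cross_validate,
    fit_predict,
    random_split,
    remove_patient_overlap,
    split_sizes,
)


class TestSplitSizes:
    def test_study_population_sizes(self):
        assert split_sizes(44_626, 0.75) == (33_469, 11_157)

    @pytest.mark.parametrize("n,frac,expected", [(4, 0.75, (3, 1)), (2, 0.5, (1, 1))])
    def test_small_cases(self, n, frac, expected):
        assert split_sizes(n, frac) == expected

    @pytest.mark.parametrize("n", range(2, 201))
    def test_sizes_are_exhaustive_and_floor(self, n):
        tr, te = split_sizes(n, 0.75)
        assert tr + te == n
        assert tr == int(np.floor(n * 0.75))

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            split_sizes(10, 1.0)


def _toy_table(n=40, seed=0, p_features=3):
    r = np.random.default_rng(seed)
    t = pd.DataFrame(r.normal(size=(n, p_features)),
                     columns=[f"x{i}" for i in range(p_features)])
    t.insert(0, "stay_id", np.arange(1, n + 1))
    t.insert(1, "patient_id", np.arange(1, n + 1))
    t["y"] = (t["x0"] > 0).astype(int)
    return t


class TestRandomSplit:
    def test_deterministic(self):
        t = _toy_table()
        a1, b1 = random_split(t, SplitSpec(seed=5))
        a2, b2 = random_split(t, SplitSpec(seed=5))
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_partition_is_exhaustive_and_disjoint(self):
        t = _toy_table(n=37)
        tr, te = random_split(t, SplitSpec(seed=1))
        assert set(tr["stay_id"]) | set(te["stay_id"]) == set(t["stay_id"])
        assert set(tr["stay_id"]) & set(te["stay_id"]) == set()

    @pytest.mark.parametrize("n", [2, 7, 50, 111])
    def test_sizes_match_split_sizes(self, n):
        t = _toy_table(n=n)
        tr, te = random_split(t, SplitSpec(seed=0))
        assert (len(tr), len(te)) == split_sizes(n, 0.75)


class TestRemovePatientOverlap:
    def test_study_overlap_arithmetic(self):
        # 3,886 of 11,157 test stays share a patient with the training set
        train = pd.DataFrame({"patient_id": np.arange(3886), "stay_id": np.arange(3886)})
        test = pd.DataFrame({
            "patient_id": np.concatenate([np.arange(3886), np.arange(10_000, 17_271)]),
            "stay_id": np.arange(11_157),
        })
        reduced, summary = remove_patient_overlap(train, test)
        assert summary["overlap_count"] == 3886
        assert summary["overlap_percent"] == 34.83
        assert summary["remaining"] == 7271
        assert len(reduced) == 7271

    def test_disjoint_patients_unchanged(self):
        train = pd.DataFrame({"patient_id": [1, 2], "stay_id": [1, 2]})
        test = pd.DataFrame({"patient_id": [3, 4], "stay_id": [3, 4]})
        reduced, summary = remove_patient_overlap(train, test)
        assert summary["overlap_percent"] == 0.0
        pd.testing.assert_frame_equal(reduced, test)


class TestCrossValidate:
    def test_separable_data_perfect_accuracy(self):
        t = _toy_table(n=100, seed=3)
        # widen the class margin so separability is unambiguous
        t["x0"] = np.where(t["y"] == 1, np.abs(t["x0"]) + 1.0, -np.abs(t["x0"]) - 1.0)
        spec = ModelSpec(algorithm="RF", hyperparameters={"n_estimators": 50})
        mean, sd = cross_validate(t, spec, SplitSpec(seed=0, k_folds=10),
                                  predictors=["x0"], outcome="y")
        assert mean == 1.0
        assert sd == 0.0

    def test_label_noise_tracks_majority_rate(self):
        r = np.random.default_rng(1)
        t = _toy_table(n=400, seed=2)
        t["y"] = r.integers(0, 2, size=len(t))  # independent of features
        spec = ModelSpec(algorithm="LR")
        mean, _ = cross_validate(t, spec, SplitSpec(seed=0, k_folds=10),
                                 predictors=["x0", "x1", "x2"], outcome="y")
        base = max(t["y"].mean(), 1 - t["y"].mean())
        se = np.sqrt(0.25 / len(t))
        assert abs(mean - base) < 6 * se

    def test_leave_one_out_layout(self):
        t = _toy_table(n=10)
        spec = ModelSpec(algorithm="LR")
        with pytest.warns(UserWarning):
            mean, sd = cross_validate(t, spec, SplitSpec(seed=0, k_folds=10),
                                      predictors=["x0"], outcome="y")
        assert 0.0 <= mean <= 1.0

    def test_too_many_folds_rejected(self):
        t = _toy_table(n=5)
        with pytest.raises(ValueError):
            cross_validate(t, ModelSpec(algorithm="LR"),
                           SplitSpec(seed=0, k_folds=10),
                           predictors=["x0"], outcome="y")


class TestFitPredict:
    def test_separable_random_forest(self):
        train = _toy_table(n=120, seed=4)
        test = _toy_table(n=40, seed=5)
        spec = ModelSpec.for_target("RF", "mortality", seed=0)
        pred = fit_predict(train, test, spec, predictors=["x0"], outcome="y")
        assert np.mean((pred >= 0.5).astype(int) == test["y"]) == 1.0

    def test_constant_outcome_regression(self):
        train = _toy_table(n=30, seed=6)
        train["days"] = 4.0
        test = _toy_table(n=10, seed=7)
        pred = fit_predict(train, test, ModelSpec(algorithm="MLR"),
                           predictors=["x0", "x1"], outcome="days")
        np.testing.assert_allclose(pred, 4.0, atol=1e-8)

    @pytest.mark.parametrize("alg", ["LR", "RF", "XGB", "SVM", "KNN", "LDA"])
    def test_deterministic_given_seed(self, alg):
        train = _toy_table(n=60, seed=8)
        test = _toy_table(n=20, seed=9)
        spec = ModelSpec(algorithm=alg,
                         hyperparameters={"n_estimators": 30} if alg == "RF" else {},
                         seed=3)
        p1 = fit_predict(train, test, spec, predictors=["x0", "x1"], outcome="y")
        p2 = fit_predict(train, test, spec, predictors=["x0", "x1"], outcome="y")
        np.testing.assert_array_equal(p1, p2)

    def test_probabilities_in_unit_interval(self):
        train = _toy_table(n=60, seed=8)
        test = _toy_table(n=20, seed=9)
        for alg in CLASSIFIERS:
            spec = ModelSpec(algorithm=alg,
                             hyperparameters={"n_estimators": 20} if alg in ("RF",) else {})
            p = fit_predict(train, test, spec, predictors=["x0", "x1"], outcome="y")
            assert np.all((p >= 0) & (p <= 1)), alg

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(algorithm="DNN")


class TestModelSpec:
    def test_tuned_hyperparameters_per_target(self):
        rf_mort = ModelSpec.for_target("RF", "mortality")
        rf_los = ModelSpec.for_target("RF", "los")
        assert rf_mort.hyperparameters["n_estimators"] == 500
        assert rf_los.hyperparameters["n_estimators"] == 400
        assert rf_mort.hyperparameters["max_features"] == 4
        svm_mort = ModelSpec.for_target("SVM", "mortality")
        svm_los = ModelSpec.for_target("SVM", "los")
        assert svm_mort.hyperparameters["C"] == 1.60
        assert svm_los.hyperparameters["C"] == 0.90

    def test_standardization_defaults(self):
        assert ModelSpec(algorithm="LR").standardize
        assert ModelSpec(algorithm="SVM").standardize
        assert not ModelSpec(algorithm="RF").standardize
        assert not ModelSpec(algorithm="XGB").standardize


class TestModelResultsFrontEnd:
    def test_mortality_model_summary(self, feature_tables):
        res = ICUOutcomeModel(
            feature_tables["quantiles"], target="mortality", mode="quantiles",
            algorithm="LR", seed=0, split=SplitSpec(seed=0, k_folds=5),
        ).fit()
        text = res.summary()
        assert "mortality" in text and "quantiles" in text
        row = res.to_row()
        assert 0.0 <= row["accuracy"] <= 1.0
        assert row["algorithm"] == "LR"

    def test_los_binary_threshold_computed(self, feature_tables):
        model = ICUOutcomeModel(
            feature_tables["baseline"], target="los_binary", mode="baseline",
            algorithm="LR", seed=0, split=SplitSpec(seed=0, k_folds=5),
        )
        assert model.los_threshold_ == pytest.approx(
            float(feature_tables["baseline"]["los_days"].median())
        )

    def test_regression_target_requires_regressor(self, feature_tables):
        with pytest.raises(ValueError):
            ICUOutcomeModel(feature_tables["baseline"], target="los_regression",
                            algorithm="RF")
        with pytest.raises(ValueError):
            ICUOutcomeModel(feature_tables["baseline"], target="mortality",
                            algorithm="SVR")

    def test_regression_results(self, feature_tables):
        res = ICUOutcomeModel(
            feature_tables["baseline"], target="los_regression", mode="baseline",
            algorithm="MLR", seed=0, split=SplitSpec(seed=0, k_folds=5),
        ).fit()
        assert res.report.rmse >= res.report.mae > 0
        assert "MAE" in res.summary()

    def test_drop_age_removes_predictor(self, feature_tables):
        model = ICUOutcomeModel(feature_tables["baseline"], target="mortality",
                                algorithm="LR", drop_age=True)
        assert "age" not in model.predictors
        assert len(model.predictors) == 11
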