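"""Experiment harness: seeded splits, 10-fold cross-validation and the eight
learning algorithms, plus a Model/Results front end.

Six binary classifiers (logistic regression, linear discriminant analysis,
random forest, k-nearest neighbours, RBF support vector machine, gradient
boosting) serve the mortality and median-split LOS targets; two regressors
(multivariate linear regression and support vector regression) serve the
continuous LOS target. Tuned hyperparameters: random forest uses at most 4
features per split with 500 trees (mortality) or 400 trees (LOS); the SVM
penalty C is 1.60 (mortality) or 0.90 (LOS). Everything else stays at the
ecosystem defaults, recorded in each spec.

The user-facing entry point follows the fit/Results idiom::

    model = ICUOutcomeModel(table, target="mortality", mode="quantiles",
                            algorithm="RF", seed=0)
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from xgboost import XGBClassifier

from .metrics import ClassificationReport, RegressionReport, regression_errors
from .outcomes import label_los_binary, los_threshold
from .quantiles import predictor_columns

__all__ = [
    "CLASSIFIERS",
    "REGRESSORS",
    "TARGETS",
    "ModelSpec",
    "SplitSpec",
    "split_sizes",
    "random_split",
    "remove_patient_overlap",
    "cross_validate",
    "fit_predict",
    "ICUOutcomeModel",
    "ICUOutcomeResults",
    "run_experiment_grid",
]

CLASSIFIERS: tuple[str, ...] = ("LR", "LDA", "RF", "KNN", "SVM", "XGB")
REGRESSORS: tuple[str, ...] = ("MLR", "SVR")
TARGETS: tuple[str, ...] = ("mortality", "los_binary", "los_regression")

#: Algorithms whose inputs are standardised to train-set mean/SD; trees and
#: boosting see raw features, and plain linear regression is scale-invariant.
_STANDARDIZED = {"LR", "LDA", "KNN", "SVM", "SVR"}


@dataclass(frozen=True)
class ModelSpec:
    """One learning algorithm with its hyperparameters.

    ``hyperparameters`` overrides the defaults below; ``standardize_inputs``
    defaults per algorithm.
    """

    algorithm: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    standardize_inputs: bool | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in CLASSIFIERS + REGRESSORS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def is_classifier(self) -> bool:
        return self.algorithm in CLASSIFIERS

    @property
    def standardize(self) -> bool:
        if self.standardize_inputs is not None:
            return self.standardize_inputs
        return self.algorithm in _STANDARDIZED

    @classmethod
    def for_target(cls, algorithm: str, target: str, seed: int = 0) -> "ModelSpec":
        """Spec with the tuned hyperparameters for a prediction target."""
        hp: dict[str, object] = {}
        if algorithm == "RF":
            hp = {"n_estimators": 500 if target == "mortality" else 400,
                  "max_features": 4}
        elif algorithm == "SVM":
            hp = {"C": 1.60 if target == "mortality" else 0.90}
        return cls(algorithm=algorithm, hyperparameters=hp, seed=seed)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split and cross-validation layout."""

    train_fraction: float = 0.75
    k_folds: int = 10
    seed: int = 0
    drop_patient_overlap: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


def split_sizes(n: int, train_fraction: float = 0.75) -> tuple[int, int]:
    """(n_train, n_test) with n_train = floor(n * fraction)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_train = int(np.floor(n * train_fraction))
    return n_train, n - n_train


def random_split(
    table: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seed-deterministic unstratified split by stay (not by patient)."""
    n_train, _ = split_sizes(len(table), spec.train_fraction)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(table))
    train = table.iloc[perm[:n_train]].reset_index(drop=True)
    test = table.iloc[perm[n_train:]].reset_index(drop=True)
    return train, test


def remove_patient_overlap(
    train_table: pd.DataFrame, test_table: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Drop test stays whose patient also appears in the training set.

    Returns the reduced test table and a summary with the overlap count and
    its percentage of the test set (2 decimals).
    """
    train_patients = set(train_table["patient_id"])
    overlap_mask = test_table["patient_id"].isin(train_patients)
    n_test = len(test_table)
    n_overlap = int(overlap_mask.sum())
    reduced = test_table.loc[~overlap_mask].reset_index(drop=True)
    summary = {
        "test_size": n_test,
        "overlap_count": n_overlap,
        "overlap_percent": round(100.0 * n_overlap / n_test, 2) if n_test else 0.0,
        "remaining": len(reduced),
    }
    return reduced, summary


def _build_estimator(spec: ModelSpec, n_features: int):
    hp = dict(spec.hyperparameters)
    alg = spec.algorithm
    if alg == "LR":
        est = LogisticRegression(max_iter=1000, **hp)
    elif alg == "LDA":
        est = LinearDiscriminantAnalysis(**hp)
    elif alg == "RF":
        hp.setdefault("n_estimators", 500)
        hp.setdefault("max_features", 4)
        hp["max_features"] = min(int(hp["max_features"]), n_features)
        est = RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    elif alg == "KNN":
        hp.setdefault("n_neighbors", 5)
        est = KNeighborsClassifier(**hp)
    elif alg == "SVM":
        hp.setdefault("C", 1.0)
        # Platt-scaled RBF SVM: probability outputs via sigmoid calibration on
        # internal folds (the classical SVC probability mechanism).
        est = CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=spec.seed, **hp),
            method="sigmoid", ensemble=False,
        )
    elif alg == "XGB":
        est = XGBClassifier(
            random_state=spec.seed, n_jobs=1, verbosity=0, eval_metric="logloss", **hp,
        )
    elif alg == "MLR":
        est = LinearRegression(**hp)
    elif alg == "SVR":
        hp.setdefault("C", 1.0)
        est = SVR(kernel="rbf", **hp)
    else:  # pragma: no cover
        raise ValueError(f"unknown algorithm {alg!r}")
    if spec.standardize:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


def _predict(est, spec: ModelSpec, X: np.ndarray) -> np.ndarray:
    if spec.is_classifier:
        return est.predict_proba(X)[:, 1]
    return est.predict(X)


def _fit(est, spec: ModelSpec, X: np.ndarray, y: np.ndarray):
    if spec.is_classifier:
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            warnings.warn(
                "single outcome class in training data; using constant predictor"
            )
            return _ConstantClassifier(float(np.mean(y)))
        if spec.algorithm == "SVM":
            # Platt scaling needs every internal fold to see both classes.
            minority = int(counts.min())
            if minority < 2:
                warnings.warn(
                    "minority class too small for probability calibration; "
                    "using constant predictor"
                )
                return _ConstantClassifier(float(np.mean(y)))
            inner = est.steps[-1][1] if isinstance(est, Pipeline) else est
            inner.set_params(cv=min(5, minority))
    est.fit(X, y)
    return est


class _ConstantClassifier:
    def __init__(self, p: float):
        self.p = p

    def predict_proba(self, X):
        p = np.full(len(X), self.p)
        return np.column_stack([1 - p, p])


def cross_validate(
    train_table: pd.DataFrame,
    spec: ModelSpec,
    split: SplitSpec,
    *,
    predictors: Sequence[str],
    outcome: str,
) -> tuple[float, float]:
    """Seeded k-fold CV on the training set.

    Per-fold metric: held-out accuracy at the 0.5 threshold for classifiers,
    held-out mean absolute error for regressors. Returns (mean, SD across
    folds).
    """
    X = train_table.loc[:, list(predictors)].to_numpy(dtype=float)
    y = train_table[outcome].to_numpy(dtype=float)
    if split.k_folds > len(train_table):
        raise ValueError("k_folds exceeds the number of training rows")
    kf = KFold(n_splits=split.k_folds, shuffle=True, random_state=split.seed)
    scores = []
    for tr_idx, te_idx in kf.split(X):
        ytr, yte = y[tr_idx], y[te_idx]
        if spec.is_classifier and np.unique(yte).size < 2:
            warnings.warn("cross-validation fold with a single outcome class")
        est = _build_estimator(spec, len(predictors))
        est = _fit(est, spec, X[tr_idx], ytr)
        pred = _predict(est, spec, X[te_idx])
        if spec.is_classifier:
            scores.append(float(np.mean((pred >= 0.5).astype(int) == yte.astype(int))))
        else:
            scores.append(float(np.mean(np.abs(pred - yte))))
    scores_arr = np.asarray(scores)
    sd = float(scores_arr.std(ddof=1)) if scores_arr.size > 1 else 0.0
    return float(scores_arr.mean()), sd


def fit_predict(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    spec: ModelSpec,
    *,
    predictors: Sequence[str],
    outcome: str,
) -> np.ndarray:
    """Fit on the training table, return per-stay test predictions.

    Classifiers return class-1 probabilities; regressors predicted days.
    Deterministic given ``spec.seed``.
    """
    Xtr = train_table.loc[:, list(predictors)].to_numpy(dtype=float)
    Xte = test_table.loc[:, list(predictors)].to_numpy(dtype=float)
    ytr = train_table[outcome].to_numpy(dtype=float)
    est = _build_estimator(spec, len(predictors))
    est = _fit(est, spec, Xtr, ytr)
    return _predict(est, spec, Xte)


# ---------------------------------------------------------------------------
# Model / Results front end


class ICUOutcomeModel:
    """One outcome-prediction experiment on a feature table.

    Parameters
    ----------
    feature_table : DataFrame
        Output of the feature assembly step: stay_id (and patient_id),
        predictor columns for the chosen mode, plus los_days and mortality.
    target : {"mortality", "los_binary", "los_regression"}
    mode : {"baseline", "quantiles"}
    algorithm : algorithm id; classifiers for the binary targets, MLR/SVR for
        the regression target.
    """

    def __init__(
        self,
        feature_table: pd.DataFrame,
        target: str = "mortality",
        mode: str = "baseline",
        algorithm: str = "RF",
        seed: int = 0,
        split: SplitSpec | None = None,
        spec: ModelSpec | None = None,
        drop_age: bool = False,
    ):
        if target not in TARGETS:
            raise ValueError(f"unknown target {target!r}")
        self.target = target
        self.mode = mode
        self.seed = seed
        self.split = split if split is not None else SplitSpec(seed=seed)
        hyper_target = "mortality" if target == "mortality" else "los"
        self.spec = (
            spec
            if spec is not None
            else ModelSpec.for_target(algorithm, hyper_target, seed=seed)
        )
        if target == "los_regression" and self.spec.is_classifier:
            raise ValueError("the regression target requires MLR or SVR")
        if target != "los_regression" and not self.spec.is_classifier:
            raise ValueError("binary targets require a classifier")

        table = feature_table.copy()
        if target == "los_binary" and "los_binary" not in table.columns:
            thr = los_threshold(table["los_days"].to_numpy())
            table["los_binary"] = label_los_binary(table["los_days"].to_numpy(), thr)
            self.los_threshold_ = thr
        else:
            self.los_threshold_ = None
        self.table = table
        self.predictors = predictor_columns(mode)
        if drop_age:
            self.predictors = [c for c in self.predictors if c != "age"]
        self.outcome = {"mortality": "mortality", "los_binary": "los_binary",
                        "los_regression": "los_days"}[target]

    def fit(self) -> "ICUOutcomeResults":
        train, test = random_split(self.table, self.split)
        overlap_summary = None
        if self.split.drop_patient_overlap:
            test, overlap_summary = remove_patient_overlap(train, test)
        cv_mean, cv_sd = cross_validate(
            train, self.spec, self.split, predictors=self.predictors,
            outcome=self.outcome,
        )
        predictions = fit_predict(
            train, test, self.spec, predictors=self.predictors, outcome=self.outcome
        )
        y_test = test[self.outcome].to_numpy(dtype=float)
        if self.spec.is_classifier:
            report = ClassificationReport.from_predictions(y_test, predictions)
        else:
            report = regression_errors(y_test, predictions)
        return ICUOutcomeResults(
            model=self,
            cv_metric_mean=cv_mean,
            cv_metric_sd=cv_sd,
            test_ids=test["stay_id"].to_numpy(),
            test_labels=y_test,
            test_predictions=predictions,
            report=report,
            overlap_summary=overlap_summary,
        )


@dataclass
class ICUOutcomeResults:
    """Fitted experiment results: CV performance, test predictions and the
    full metric report."""

    model: ICUOutcomeModel
    cv_metric_mean: float
    cv_metric_sd: float
    test_ids: np.ndarray
    test_labels: np.ndarray
    test_predictions: np.ndarray
    report: ClassificationReport | RegressionReport
    overlap_summary: dict | None = None

    @property
    def is_classifier(self) -> bool:
        return self.model.spec.is_classifier

    def to_row(self) -> dict:
        """One flat result row (the report-table form)."""
        row = {
            "target": self.model.target,
            "mode": self.model.mode,
            "algorithm": self.model.spec.algorithm,
            "cv_metric_mean": self.cv_metric_mean,
            "cv_metric_sd": self.cv_metric_sd,
            "n_test": int(len(self.test_ids)),
        }
        if self.is_classifier:
            for name, m in self.report.metrics.items():
                row[name] = m.point
                row[f"{name}_ci_low"] = m.ci_low
                row[f"{name}_ci_high"] = m.ci_high
            row["auroc"] = self.report.auroc
            row["calibration_slope"] = self.report.calibration_slope
            row["calibration_intercept"] = self.report.calibration_intercept
        else:
            row["mae"] = self.report.mae
            row["rmse"] = self.report.rmse
        return row

    def summary(self) -> str:
        """Human-readable summary table."""
        m = self.model
        lines = [
            "ICU outcome prediction results",
            "=" * 46,
            f"target:            {m.target}",
            f"feature mode:      {m.mode} ({len(m.predictors)} predictors)",
            f"algorithm:         {m.spec.algorithm}",
            f"split:             {m.split.train_fraction:.0%} train, "
            f"{m.split.k_folds}-fold CV, seed {m.split.seed}",
            f"test stays:        {len(self.test_ids)}",
        ]
        if self.overlap_summary:
            lines.append(
                f"patient overlap:   {self.overlap_summary['overlap_count']} removed "
                f"({self.overlap_summary['overlap_percent']}% of test)"
            )
        cv_name = "accuracy" if self.is_classifier else "MAE"
        lines.append(
            f"CV {cv_name}:       {self.cv_metric_mean:.4f} (SD {self.cv_metric_sd:.4f})"
        )
        lines.append("-" * 46)
        if self.is_classifier:
            for name, est in self.report.metrics.items():
                if est.defined():
                    lines.append(
                        f"{name:<13s} {est.point:.4f}  ({est.ci_low:.3f}-{est.ci_high:.3f})"
                    )
                else:
                    lines.append(f"{name:<13s} undefined")
            lines.append(f"{'auroc':<13s} {self.report.auroc:.5f}")
            lines.append(
                f"calibration   slope {self.report.calibration_slope:.3f}, "
                f"intercept {self.report.calibration_intercept:.3f}"
            )
        else:
            lines.append(f"MAE   {self.report.mae:.3f} days")
            lines.append(f"RMSE  {self.report.rmse:.3f} days")
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_roc(self, ax=None):
        """ROC curve of the test-set predictions."""
        import matplotlib.pyplot as plt

        if not self.is_classifier:
            raise ValueError("ROC is only defined for classifiers")
        if ax is None:
            _, ax = plt.subplots()
        pts = self.report.roc_points
        ax.plot(pts[:, 0], pts[:, 1],
                label=f"{self.model.spec.algorithm} (AUROC {self.report.auroc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        return ax

    def plot_calibration(self, ax=None):
        """Decile reliability diagram of the test-set probabilities."""
        import matplotlib.pyplot as plt

        if not self.is_classifier:
            raise ValueError("calibration is only defined for classifiers")
        if ax is None:
            _, ax = plt.subplots()
        t = self.report.calibration
        ax.plot(t["mean_predicted"], t["observed_rate"], "o-")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("Mean predicted probability")
        ax.set_ylabel("Observed event rate")
        return ax


def run_experiment_grid(
    tables: Mapping[str, pd.DataFrame],
    seed: int = 0,
    split: SplitSpec | None = None,
    algorithms: Sequence[str] | None = None,
    drop_age: bool = False,
) -> pd.DataFrame:
    """The full result grid: {mortality, LOS-binary} x {baseline, quantiles} x
    six classifiers, plus LOS-regression x both modes x two regressors —
    28 rows with the default algorithm list.

    ``tables`` maps feature mode -> assembled feature table.
    """
    split = split if split is not None else SplitSpec(seed=seed)
    rows = []
    cls_algs = [a for a in (algorithms or CLASSIFIERS) if a in CLASSIFIERS]
    reg_algs = [a for a in (algorithms or REGRESSORS) if a in REGRESSORS]
    for target in ("mortality", "los_binary"):
        for mode, table in tables.items():
            for alg in cls_algs:
                res = ICUOutcomeModel(
                    table, target=target, mode=mode, algorithm=alg, seed=seed,
                    split=split, drop_age=drop_age,
                ).fit()
                rows.append(res.to_row())
    for mode, table in tables.items():
        for alg in reg_algs:
            res = ICUOutcomeModel(
                table, target="los_regression", mode=mode, algorithm=alg, seed=seed,
                split=split, drop_age=drop_age,
            ).fit()
            rows.append(res.to_row())
    return pd.DataFrame(rows)
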