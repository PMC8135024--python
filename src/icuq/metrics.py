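"""Classification and regression metrics with confidence intervals.

Covers the full report surface: accuracy / sensitivity / specificity / NPV /
PPV with 95% CIs, AUROC with the ROC curve, decile calibration with a
logistic recalibration (slope/intercept) check, and MAE/RMSE for regression.

The CI default is the unclipped Wald interval p +/- z*sqrt(p(1-p)/n): upper
bounds above 1 are reported as computed (this matches how such intervals are
commonly printed for near-perfect specificity); a clipped Wilson interval is
available via ``method='wilson'``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

import statsmodels.api as sm

__all__ = [
    "ConfusionCounts",
    "MetricEstimate",
    "ClassificationReport",
    "RegressionReport",
    "confusion_metrics",
    "auroc",
    "roc_curve",
    "calibration_deciles",
    "regression_errors",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts; the positive class is the adverse outcome
    (death, or LOS above the median)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts must sum to at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its confidence interval; NaN when undefined."""

    point: float
    ci_low: float
    ci_high: float

    def defined(self) -> bool:
        return not math.isnan(self.point)


def _proportion_ci(
    k: int, n: int, confidence: float, method: str
) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(math.nan, math.nan, math.nan)
    p = k / n
    z = norm.ppf(0.5 + confidence / 2.0)
    if method == "wald":
        half = z * math.sqrt(p * (1.0 - p) / n)
        return MetricEstimate(p, p - half, p + half)  # deliberately unclipped
    if method == "wilson":
        denom = 1.0 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        return MetricEstimate(p, max(0.0, center - half), min(1.0, center + half))
    raise ValueError(f"unknown CI method {method!r}")


def confusion_metrics(
    counts: ConfusionCounts, confidence: float = 0.95, method: str = "wald"
) -> dict[str, MetricEstimate]:
    """Accuracy, sensitivity, specificity, NPV and PPV with CIs.

    Metrics with a zero denominator are reported as undefined (NaN), never
    as 0.
    """
    c = counts
    pairs = {
        "accuracy": (c.tp + c.tn, c.total),
        "sensitivity": (c.tp, c.tp + c.fn),
        "specificity": (c.tn, c.tn + c.fp),
        "npv": (c.tn, c.tn + c.fn),
        "ppv": (c.tp, c.tp + c.fp),
    }
    return {
        name: _proportion_ci(k, n, confidence, method) for name, (k, n) in pairs.items()
    }


def _check_two_classes(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both outcome classes must be present")


def auroc(labels: Sequence[int] | np.ndarray, scores: Sequence[float] | np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney formulation, ties count 1/2)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def roc_curve(
    labels: Sequence[int] | np.ndarray, scores: Sequence[float] | np.ndarray
) -> np.ndarray:
    """ROC points as an (k, 2) array of (fpr, tpr), from (0,0) to (1,1)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(labels)
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    points = np.column_stack([fpr, tpr])
    if not np.allclose(points[0], (0.0, 0.0)):
        points = np.vstack([(0.0, 0.0), points])
    if not np.allclose(points[-1], (1.0, 1.0)):
        points = np.vstack([points, (1.0, 1.0)])
    return points


def calibration_deciles(
    labels: Sequence[int] | np.ndarray,
    probabilities: Sequence[float] | np.ndarray,
    n_bins: int = 10,
    eps: float = 1e-6,
) -> tuple[pd.DataFrame, float, float]:
    """Decile reliability table plus a logistic recalibration check.

    Rows are ``n_bins`` equal-count, probability-ranked bins with the mean
    predicted probability, the observed event rate and the bin count. The
    recalibration fits outcome ~ logit(clipped probability) by maximum
    likelihood; a perfectly calibrated model gives slope ~ 1, intercept ~ 0.

    Returns (table, slope, intercept).
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    _check_two_classes(y)
    n = y.size
    if n < n_bins:
        warnings.warn(f"only {n} observations: using {n} calibration bins")
        n_bins = n
    order = np.argsort(p, kind="stable")
    bins = np.array_split(order, n_bins)
    rows = [
        {
            "bin": i + 1,
            "mean_predicted": float(p[idx].mean()),
            "observed_rate": float(y[idx].mean()),
            "n": int(idx.size),
        }
        for i, idx in enumerate(bins)
    ]
    table = pd.DataFrame(rows)

    logit_p = np.log(np.clip(p, eps, 1.0 - eps) / (1.0 - np.clip(p, eps, 1.0 - eps)))
    if np.ptp(logit_p) == 0.0:
        # constant predictions: the recalibration slope is undefined
        warnings.warn("constant predicted probabilities; recalibration undefined")
        return table, math.nan, math.nan
    X = sm.add_constant(logit_p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, method="lbfgs", maxiter=500)
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    return table, slope, intercept


@dataclass(frozen=True)
class RegressionReport:
    """Regression error bundle, in days."""

    mae: float
    rmse: float


def regression_errors(
    true_days: Sequence[float] | np.ndarray, predicted_days: Sequence[float] | np.ndarray
) -> RegressionReport:
    """Mean absolute error and root mean squared error."""
    t = np.asarray(true_days, dtype=float)
    p = np.asarray(predicted_days, dtype=float)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("true and predicted values must have equal, nonzero length")
    err = p - t
    return RegressionReport(
        mae=float(np.mean(np.abs(err))), rmse=float(np.sqrt(np.mean(err**2)))
    )


@dataclass
class ClassificationReport:
    """Full classification report: five CI'd metrics, AUROC, ROC points and
    the decile calibration table with its recalibration slope/intercept."""

    metrics: dict[str, MetricEstimate]
    auroc: float
    roc_points: np.ndarray
    calibration: pd.DataFrame
    calibration_slope: float
    calibration_intercept: float

    @classmethod
    def from_predictions(
        cls,
        labels: np.ndarray,
        probabilities: np.ndarray,
        threshold: float = 0.5,
        confidence: float = 0.95,
        ci_method: str = "wald",
    ) -> "ClassificationReport":
        labels = np.asarray(labels).astype(int)
        probabilities = np.asarray(probabilities, dtype=float)
        counts = ConfusionCounts.from_labels(labels, probabilities >= threshold)
        if np.unique(labels).size < 2:
            # Degenerate (tiny) test sets: rank- and calibration-based metrics
            # are undefined; report NaN rather than fail the whole run.
            warnings.warn("single outcome class in test labels; AUROC/calibration undefined")
            return cls(
                metrics=confusion_metrics(counts, confidence, ci_method),
                auroc=math.nan,
                roc_points=np.array([[0.0, 0.0], [1.0, 1.0]]),
                calibration=pd.DataFrame(
                    columns=["bin", "mean_predicted", "observed_rate", "n"]
                ),
                calibration_slope=math.nan,
                calibration_intercept=math.nan,
            )
        table, slope, intercept = calibration_deciles(labels, probabilities)
        return cls(
            metrics=confusion_metrics(counts, confidence, ci_method),
            auroc=auroc(labels, probabilities),
            roc_points=roc_curve(labels, probabilities),
            calibration=table,
            calibration_slope=slope,
            calibration_intercept=intercept,
        )

    def to_dict(self) -> dict:
        out = {
            name: {"point": m.point, "ci_low": m.ci_low, "ci_high": m.ci_high}
            for name, m in self.metrics.items()
        }
        out["auroc"] = self.auroc
        out["calibration_slope"] = self.calibration_slope
        out["calibration_intercept"] = self.calibration_intercept
        return out
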