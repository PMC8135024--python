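"""Tail-quantile feature engineering for per-stay vital-sign series.

The transform emphasises the extremes of each stay's distribution of one
vital, on the argument that clinical deterioration shows up as unusually high
or low readings rather than as a shift of the typical value. For each vital
within each stay:

1. fit a normal by the sample mean and SD of the stay's observations;
2. take the fitted distribution's percent point function (inverse CDF) at a
   low and a high probability (defaults 0.25 and 0.75) to get two cutoffs;
3. keep only the observations below the low cutoff or at/above the high
   cutoff (the "first and fourth quantiles" of the fitted distribution);
4. summarise the retained tail observations by their mean ("modified mean"),
   their sample SD ("modified SD") and the fraction of the stay's
   observations retained (the "quantile percentage").

This yields 3 engineered features per vital, 21 per stay, appended to the 12
baseline predictors when the engineered feature mode is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .prep import BASELINE_PREDICTORS
from .synth import VITALS, StayRecord

__all__ = [
    "QuantileConfig",
    "NormalFit",
    "QUANTILE_FEATURES",
    "fit_normal",
    "tail_cutoffs",
    "extract_tails",
    "modified_stats",
    "quantile_percentage",
    "engineer_stay",
    "engineer_table",
    "assemble_feature_table",
]

#: Engineered column names per vital, following the published feature schema
#: (mixed capitalisation included): (mean_mod, std_mod, quant_per).
QUANTILE_FEATURE_NAMES: dict[str, tuple[str, str, str]] = {
    "heartrate": ("HeartRate_mean_mod", "heartRate_std_mod", "HeartRateQuantPer"),
    "sysbp": ("sysbp_mean_mod", "sysbp_std_mod", "SystolicQuantPer"),
    "diasbp": ("diasbp_mean_mod", "diasbp_std_mod", "DiastolicQuantPer"),
    "resprate": ("resprate_mean_mod", "resprate_std_mod", "RespRateQuantPer"),
    "tempc": ("tempc_mean_mod", "tempc_std_mod", "TempCQuantPer"),
    "spo2": ("spo2_mean_mod", "spo2_std_mod", "SPO2QuantPer"),
    "glucose": ("glucose_mean_mod", "glucose_std_mod", "GlucoseQuantPer"),
}

#: The 21 engineered columns in fixed order (7 vitals x 3 features).
QUANTILE_FEATURES: tuple[str, ...] = tuple(
    name for v in VITALS for name in QUANTILE_FEATURE_NAMES[v]
)


@dataclass(frozen=True)
class QuantileConfig:
    """Probabilities of the low/high inverse-CDF cutoffs and the minimum tail
    count for a defined sample SD."""

    p_low: float = 0.25
    p_high: float = 0.75
    min_tail_count: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.p_low < self.p_high < 1.0:
            raise ValueError(
                f"require 0 < p_low < p_high < 1, got ({self.p_low}, {self.p_high})"
            )


@dataclass(frozen=True)
class NormalFit:
    """Per-sample normal fit: the sample mean and sample SD (ddof=1)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def fit_normal(values: Sequence[float] | np.ndarray) -> NormalFit:
    """Fit mean and sample SD; SD is 0 for a single observation."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("cannot fit a normal to an empty sample")
    sd = float(np.std(v, ddof=1)) if v.size >= 2 else 0.0
    return NormalFit(mean=float(np.mean(v)), sd=sd)


def tail_cutoffs(
    fit: NormalFit, config: QuantileConfig = QuantileConfig()
) -> tuple[float, float]:
    """Inverse-CDF cutoffs of Normal(fit.mean, fit.sd) at p_low and p_high.

    Degenerate fits (sd = 0) collapse both cutoffs onto the mean.
    """
    if fit.sd == 0.0:
        return fit.mean, fit.mean
    low = float(norm.ppf(config.p_low, loc=fit.mean, scale=fit.sd))
    high = float(norm.ppf(config.p_high, loc=fit.mean, scale=fit.sd))
    return low, high


def extract_tails(
    values: Sequence[float] | np.ndarray, low: float, high: float
) -> np.ndarray:
    """Observations strictly below ``low`` or at/above ``high``, order kept.

    With ``low == high`` every value satisfies one of the two conditions, so
    the whole sample is returned (the documented sd = 0 degeneracy).
    """
    if low > high:
        raise ValueError("require low <= high")
    v = np.asarray(values, dtype=float)
    return v[(v < low) | (v >= high)]


def modified_stats(
    tail_values: Sequence[float] | np.ndarray,
    fallback: NormalFit,
    config: QuantileConfig = QuantileConfig(),
) -> tuple[float, float]:
    """Mean and sample SD of the tail observations.

    A single tail observation yields (value, 0); an empty tail falls back to
    (full-sample mean, 0) so the feature stays defined for every stay.
    """
    v = np.asarray(tail_values, dtype=float)
    if v.size == 0:
        return fallback.mean, 0.0
    if v.size < config.min_tail_count:
        warnings.warn("tail count below min_tail_count; modified SD reported as 0")
        return float(v.mean()), 0.0
    return float(v.mean()), float(np.std(v, ddof=1))


def quantile_percentage(tail_count: int, total_count: int) -> float:
    """Fraction of the stay's observations that fall in the two tails."""
    if total_count < 1:
        raise ValueError("total_count must be >= 1")
    if not 0 <= tail_count <= total_count:
        raise ValueError("require 0 <= tail_count <= total_count")
    return tail_count / total_count


def engineer_stay(
    stay: StayRecord, config: QuantileConfig = QuantileConfig()
) -> dict[str, float]:
    """The 21 engineered features for one cleaned, first-day stay.

    Vitals with no retained observations yield NaN features (imputed later at
    the table level).
    """
    row: dict[str, float] = {"stay_id": stay.stay_id}
    for v in VITALS:
        mean_col, sd_col, per_col = QUANTILE_FEATURE_NAMES[v]
        obs = stay.series[v].observed_values()
        if obs.size == 0:
            row[mean_col] = row[sd_col] = row[per_col] = np.nan
            continue
        fit = fit_normal(obs)
        low, high = tail_cutoffs(fit, config)
        tails = extract_tails(obs, low, high)
        mean_mod, std_mod = modified_stats(tails, fit, config)
        row[mean_col] = mean_mod
        row[sd_col] = std_mod
        row[per_col] = quantile_percentage(tails.size, obs.size)
    return row


def engineer_table(
    stays: Sequence[StayRecord], config: QuantileConfig = QuantileConfig()
) -> pd.DataFrame:
    """Engineered feature rows for a cohort, keyed by stay_id."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-stay min_tail_count warnings
        rows = [engineer_stay(s, config) for s in stays]
    return pd.DataFrame(rows, columns=["stay_id", *QUANTILE_FEATURES])


def assemble_feature_table(
    baseline_table: pd.DataFrame,
    quantile_rows: pd.DataFrame | None,
    mode: str,
) -> pd.DataFrame:
    """Join baseline and engineered features into the modelling table.

    ``mode='baseline'`` keeps the 12 baseline predictors; ``mode='quantiles'``
    appends the 21 engineered columns (33 predictors). Outcome columns
    (los_days, mortality) and ids are carried through. Column order is fixed.
    """
    if mode not in ("baseline", "quantiles"):
        raise ValueError(f"mode must be 'baseline' or 'quantiles', got {mode!r}")
    id_cols = ["stay_id"] + (["patient_id"] if "patient_id" in baseline_table else [])
    outcome_cols = [c for c in ("los_days", "mortality") if c in baseline_table]
    base = baseline_table.loc[:, id_cols + list(BASELINE_PREDICTORS) + outcome_cols]
    if mode == "baseline":
        table = base
    else:
        if quantile_rows is None:
            raise ValueError("quantiles mode requires engineered feature rows")
        if set(base["stay_id"]) != set(quantile_rows["stay_id"]):
            raise ValueError("stay_id mismatch between baseline and engineered rows")
        table = base.merge(
            quantile_rows.loc[:, ["stay_id", *QUANTILE_FEATURES]],
            on="stay_id",
            how="inner",
            validate="one_to_one",
        )
        # keep outcomes last
        table = table.loc[
            :,
            id_cols
            + list(BASELINE_PREDICTORS)
            + list(QUANTILE_FEATURES)
            + outcome_cols,
        ]
    return table.reset_index(drop=True)


def predictor_columns(mode: str) -> list[str]:
    """Predictor column names for a feature mode (12 or 33 columns)."""
    if mode == "baseline":
        return list(BASELINE_PREDICTORS)
    if mode == "quantiles":
        return list(BASELINE_PREDICTORS) + list(QUANTILE_FEATURES)
    raise ValueError(f"unknown feature mode {mode!r}")
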