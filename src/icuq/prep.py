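"""Cohort selection, cleaning, aggregation and imputation.

Mirrors a standard first-day ICU extraction: keep stays of at least one day,
truncate every observation series to the first 24 hours, drop physiologically
implausible readings, summarise each vital by its per-stay mean, one-hot
encode gender, and mean-impute any remaining missing feature values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synth import VITALS, StayRecord, VitalObservationSeries

__all__ = [
    "CleaningRules",
    "DEFAULT_CLEANING_RULES",
    "filter_first_day",
    "clean_observations",
    "clean_stay",
    "cap_age",
    "aggregate_baseline",
    "impute_mean",
    "describe_cohort",
    "pearson_matrix",
    "BASELINE_PREDICTORS",
]

FIRST_DAY_HOURS = 24.0
AGE_CAP = 90.0

#: Baseline predictor column order: 7 vital means + 5 demographics.
BASELINE_PREDICTORS: tuple[str, ...] = (
    "heartrate_mean",
    "sysbp_mean",
    "diasbp_mean",
    "resprate_mean",
    "tempc_mean",
    "spo2_mean",
    "glucose_mean",
    "age",
    "genderM",
    "genderF",
    "height",
    "weight",
)


class CleaningConfigError(KeyError):
    """A vital is absent from the cleaning rules."""


@dataclass(frozen=True)
class CleaningRules:
    """Inclusive per-vital plausibility ranges, in each vital's units.

    The ranges are assumptions (the plausible-physiology defaults below), not
    published thresholds, and are fully configurable.
    """

    ranges: Mapping[str, tuple[float, float]]
    drop_nonpositive: bool = True

    def __post_init__(self) -> None:
        for name, (low, high) in self.ranges.items():
            if not np.isfinite([low, high]).all() or not low < high:
                raise ValueError(f"invalid range for {name!r}: ({low}, {high})")

    def range_for(self, vital_name: str) -> tuple[float, float]:
        try:
            return self.ranges[vital_name]
        except KeyError:
            raise CleaningConfigError(
                f"no cleaning range configured for vital {vital_name!r}"
            ) from None


DEFAULT_CLEANING_RULES = CleaningRules(
    ranges={
        "heartrate": (1.0, 300.0),  # bpm
        "resprate": (1.0, 70.0),  # breaths/min
        "sysbp": (1.0, 400.0),  # mmHg
        "diasbp": (1.0, 300.0),  # mmHg
        "spo2": (1.0, 100.0),  # %
        "tempc": (25.0, 45.0),  # deg C
        "glucose": (1.0, 2000.0),  # mg/dL
    }
)


def filter_first_day(stays: Iterable[StayRecord]) -> list[StayRecord]:
    """Keep stays with LOS >= 1 day and truncate series to hours [0, 24).

    Idempotent; returns new StayRecords, inputs are not mutated.
    """
    out: list[StayRecord] = []
    for stay in stays:
        if stay.los_days < 1.0:
            continue
        series = {}
        for name, s in stay.series.items():
            keep = (s.times >= 0.0) & (s.times < FIRST_DAY_HOURS)
            series[name] = VitalObservationSeries(name, s.times[keep], s.values[keep])
        out.append(
            StayRecord(
                stay_id=stay.stay_id,
                patient_id=stay.patient_id,
                age=stay.age,
                gender=stay.gender,
                height=stay.height,
                weight=stay.weight,
                los_days=stay.los_days,
                mortality=stay.mortality,
                series=series,
            )
        )
    return out


def clean_observations(
    series: VitalObservationSeries, rules: CleaningRules = DEFAULT_CLEANING_RULES
) -> VitalObservationSeries:
    """Drop implausible readings: outside the vital's range, non-positive
    (when configured), or non-finite. Missing (NaN) markers are dropped too —
    imputation happens later at the feature-table level. Order is preserved."""
    low, high = rules.range_for(series.vital_name)
    v = series.values
    with np.errstate(invalid="ignore"):
        keep = np.isfinite(v) & (v >= low) & (v <= high)
        if rules.drop_nonpositive:
            keep &= v > 0
    return VitalObservationSeries(series.vital_name, series.times[keep], v[keep])


def clean_stay(stay: StayRecord, rules: CleaningRules = DEFAULT_CLEANING_RULES) -> StayRecord:
    """Apply :func:`clean_observations` to every series of a stay."""
    return StayRecord(
        stay_id=stay.stay_id,
        patient_id=stay.patient_id,
        age=stay.age,
        gender=stay.gender,
        height=stay.height,
        weight=stay.weight,
        los_days=stay.los_days,
        mortality=stay.mortality,
        series={name: clean_observations(s, rules) for name, s in stay.series.items()},
    )


def cap_age(age: float) -> float:
    """Cap age at 90 years (the de-identification dummy for ages > 89)."""
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    return min(float(age), AGE_CAP)


def aggregate_baseline(stays: Sequence[StayRecord]) -> pd.DataFrame:
    """One row per stay: per-vital first-day means + demographics.

    Vital columns are NaN when the stay has no retained observations for that
    vital (imputed later). Also carries patient_id and the outcome columns for
    downstream joins.
    """
    ids = [s.stay_id for s in stays]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate stay_id in cohort")
    rows = []
    for stay in stays:
        row: dict[str, float] = {"stay_id": stay.stay_id, "patient_id": stay.patient_id}
        for v in VITALS:
            obs = stay.series[v].observed_values()
            row[f"{v}_mean"] = float(np.mean(obs)) if obs.size else np.nan
        row["age"] = cap_age(stay.age)
        row["genderM"] = 1 if stay.gender == "M" else 0
        row["genderF"] = 0 if stay.gender == "M" else 1
        row["height"] = stay.height
        row["weight"] = stay.weight
        row["los_days"] = stay.los_days
        row["mortality"] = stay.mortality
        rows.append(row)
    cols = ["stay_id", "patient_id", *BASELINE_PREDICTORS, "los_days", "mortality"]
    return pd.DataFrame(rows, columns=cols)


class ImputationError(ValueError):
    """A column to impute has no observed values."""


def impute_mean(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Replace missing entries in ``columns`` by each column's observed mean.

    Leaves non-missing entries untouched; the column mean is unchanged.
    """
    out = table.copy()
    for col in columns:
        vals = out[col]
        if vals.isna().all():
            raise ImputationError(f"column {col!r} is entirely missing")
        if vals.isna().any():
            out[col] = vals.fillna(vals.mean())
    return out


def describe_cohort(table: pd.DataFrame) -> dict:
    """Descriptive statistics for a feature table with outcomes.

    Numeric columns get mean and sample SD (n-1; reported as 0.0 with a
    warning for single rows); gender columns get n and percentage (2 dp);
    LOS gets min/median/mean; the mortality prevalence is reported in percent.
    """
    if len(table) == 0:
        raise ValueError("cannot describe an empty table")
    n = len(table)
    report: dict = {"n_stays": n, "columns": {}}
    for col in table.columns:
        if col in ("stay_id", "patient_id"):
            continue
        vals = table[col]
        if col in ("genderM", "genderF"):
            count = int(vals.sum())
            report["columns"][col] = {
                "n": count,
                "percent": round(100.0 * count / n, 2),
            }
            continue
        if not pd.api.types.is_numeric_dtype(vals):
            continue
        if n < 2:
            warnings.warn(f"single-row table: SD for {col!r} reported as 0.0")
            sd = 0.0
        else:
            sd = float(vals.std(ddof=1))
        report["columns"][col] = {"mean": float(vals.mean()), "sd": sd}
    if "los_days" in table.columns:
        los = table["los_days"]
        report["los"] = {
            "min": float(los.min()),
            "median": float(los.median()),
            "mean": float(los.mean()),
        }
    if "mortality" in table.columns:
        report["mortality_percent"] = round(100.0 * float(table["mortality"].mean()), 3)
    return report


def pearson_matrix(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Pearson correlation matrix over the named numeric columns.

    Raises on zero-variance columns (the correlation is undefined there).
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows for correlations")
    X = table.loc[:, list(columns)].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    for name, s in zip(columns, sd):
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"correlation undefined: column {name!r} has zero variance")
    corr = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=list(columns), columns=list(columns))
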