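"""Synthetic ICU cohort generator.

Emulates a first-day ICU vital-sign extraction: each stay carries timestamped
observations for seven vitals (heart rate, systolic/diastolic blood pressure,
respiration rate, body temperature, SpO2, glucose), demographics, a length of
stay in days and an in-hospital mortality flag.

The generative model is deliberately simple but carries the two signal channels
the downstream feature engineering is designed to separate:

* a latent per-stay severity score ``s ~ N(0, 1)`` that shifts the *level* of
  each vital (tachycardia, hypotension, desaturation ... for high ``s``), and
* transient **tail excursions**: individual observations displaced by a few
  population SDs, whose per-observation probability grows with severity.

Mortality follows a logistic model in severity and the stay's realized
excursion fraction (``tail burden``); length of stay is a clipped lognormal
with a severity term. Defaults are calibrated so that a large default cohort
reproduces the population statistics the analysis assumes: per-vital means
near their population values, median LOS near 2.64 days and in-hospital
mortality near 11.897%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VITALS",
    "CohortConfig",
    "VitalObservationSeries",
    "StayRecord",
    "generate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "cohort_to_frames",
    "frames_to_cohort",
]

#: Canonical vital-sign names, in fixed column order.
VITALS: tuple[str, ...] = (
    "heartrate",
    "sysbp",
    "diasbp",
    "resprate",
    "tempc",
    "spo2",
    "glucose",
)

# Population (mean, SD) per vital, in each vital's units. SpO2 has no published
# population SD in the source cohort's descriptive table; 2.0% is an assumed
# value of plausible magnitude.
_DEFAULT_VITAL_PARAMS: dict[str, tuple[float, float]] = {
    "heartrate": (85.99, 15.59),  # beats/min
    "sysbp": (118.75, 16.90),  # mmHg
    "diasbp": (60.47, 10.89),  # mmHg
    "resprate": (18.93, 4.05),  # breaths/min
    "tempc": (36.84, 0.62),  # deg C
    "spo2": (97.27, 2.0),  # %
    "glucose": (138.74, 41.86),  # mg/dL
}

# Severity loading on the vital's level, in vital units per unit severity.
# Signs follow clinical deterioration: heart rate, respiration, temperature and
# glucose rise; blood pressures and SpO2 fall.
_DEFAULT_SEVERITY_EFFECT: dict[str, float] = {
    "heartrate": 6.0,
    "sysbp": -7.0,
    "diasbp": -4.0,
    "resprate": 1.6,
    "tempc": 0.20,
    "spo2": -1.0,
    "glucose": 15.0,
}

# (per-observation excursion probability at severity 0, magnitude in population SDs)
_DEFAULT_TAIL_EXCURSION: dict[str, tuple[float, float]] = {
    v: (0.04, 2.5) for v in VITALS
}

# Mortality intercept: Monte-Carlo calibrated (n=200,000 stays of latent draws)
# so that mean inverse-logit(intercept + a*s + b*tail_burden) = 0.11897 under
# the default a, b and excursion parameters. See scratch/calibrate_generator.py.
_CALIBRATED_MORTALITY_INTERCEPT = -2.692502

# Lognormal LOS: median exp(mu) = 2.64 days; total log-scale SD
# sqrt(los_log_sd^2 + los_severity_coef^2) ~ 1.084 gives an unclipped mean of
# ~4.75 days; clipping to [1, 173.07] leaves the median untouched.
_LOS_LOG_MEAN = math.log(2.64)
_LOS_SEVERITY_COEF = 0.35
_LOS_LOG_SD = math.sqrt(2.0 * math.log(4.74959 / 2.64) - _LOS_SEVERITY_COEF**2)

LOS_MIN_DAYS = 1.0
LOS_MAX_DAYS = 173.07


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    All per-vital mappings must cover exactly the seven canonical vitals.
    ``severity_effect`` is in vital units per unit latent severity;
    ``tail_excursion`` maps each vital to ``(probability, magnitude_in_SDs)``.
    Mortality coefficients are on the log-odds scale; LOS parameters on the
    log-days scale.
    """

    n_stays: int = 1000
    seed: int = 0
    obs_per_day: int = 24
    vital_population_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_VITAL_PARAMS)
    )
    severity_effect: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SEVERITY_EFFECT)
    )
    tail_excursion: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TAIL_EXCURSION)
    )
    #: Log-scale multiplier of severity on the excursion probability:
    #: p_eff = clip(p * exp(scale * s), 0, 0.9). 0 makes excursions severity-free.
    excursion_severity_scale: float = 0.6
    mortality_intercept: float = _CALIBRATED_MORTALITY_INTERCEPT
    mortality_severity_coef: float = 0.9
    mortality_tailburden_coef: float = 6.0
    los_log_mean: float = _LOS_LOG_MEAN
    los_log_sd: float = _LOS_LOG_SD
    los_severity_coef: float = _LOS_SEVERITY_COEF
    missing_rate: float = 0.01
    age_params: tuple[float, float] = (64.35, 16.87)
    age_range: tuple[float, float] = (18.0, 90.0)
    height_params: tuple[float, float] = (160.66, 11.76)
    weight_params: tuple[float, float] = (80.45, 23.47)
    male_fraction: float = 0.5656
    #: Fraction of patients with a single ICU stay; the rest get 1 + Geometric
    #: extra stays.
    single_stay_fraction: float = 0.8

    def validate(self) -> None:
        if self.n_stays < 0:
            raise ConfigurationError("n_stays must be non-negative")
        if self.obs_per_day < 2:
            raise ConfigurationError("obs_per_day must be >= 2")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        for name in VITALS:
            if name not in self.vital_population_params:
                raise ConfigurationError(f"missing population params for vital {name!r}")
            if name not in self.severity_effect:
                raise ConfigurationError(f"missing severity effect for vital {name!r}")
            prob, mag = self.tail_excursion[name]
            if not 0.0 <= prob < 1.0:
                raise ConfigurationError(
                    f"tail excursion probability for {name!r} must be in [0, 1)"
                )
            if not np.isfinite([prob, mag]).all():
                raise ConfigurationError(f"non-finite tail excursion for {name!r}")
            mean, sd = self.vital_population_params[name]
            if not np.isfinite([mean, sd]).all() or sd < 0:
                raise ConfigurationError(f"invalid population params for {name!r}")
        scalars = [
            self.excursion_severity_scale,
            self.mortality_intercept,
            self.mortality_severity_coef,
            self.mortality_tailburden_coef,
            self.los_log_mean,
            self.los_log_sd,
            self.los_severity_coef,
        ]
        if not np.isfinite(scalars).all():
            raise ConfigurationError("non-finite model coefficient in config")

    def with_(self, **kwargs) -> "CohortConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class VitalObservationSeries:
    """Timestamped observations of one vital for one ICU stay.

    ``times`` are hours since ICU admission, ascending; ``values`` may contain
    NaN for missing observations.
    """

    vital_name: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.vital_name not in VITALS:
            raise ValueError(f"unknown vital name {self.vital_name!r}")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError("times must be ascending")

    def __len__(self) -> int:
        return int(self.times.size)

    def observed_values(self) -> np.ndarray:
        """Values with missing (NaN) entries dropped, order preserved."""
        return self.values[~np.isnan(self.values)]


@dataclass
class StayRecord:
    """One unique ICU stay with demographics, outcomes and 7 vital series."""

    stay_id: int
    patient_id: int
    age: float
    gender: str  # "M" or "F"
    height: float  # cm
    weight: float  # kg
    los_days: float
    mortality: int  # 1 = in-hospital death
    series: dict[str, VitalObservationSeries]
    #: Realized excursion fraction (generator diagnostic; NaN for cohorts
    #: read back from CSV).
    tail_burden: float = float("nan")

    def __post_init__(self) -> None:
        if self.gender not in ("M", "F"):
            raise ValueError(f"gender must be 'M' or 'F', got {self.gender!r}")
        if self.mortality not in (0, 1):
            raise ValueError("mortality must be 0 or 1")


def _assign_patients(n_stays: int, cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Map stay index -> patient index; ~80% of patients have one stay."""
    if n_stays == 0:
        return np.zeros(0, dtype=int)
    # Draw generously many patients, then cut at n_stays.
    u_single = rng.random(n_stays)
    extra = rng.geometric(0.5, size=n_stays)  # >= 1
    counts = np.where(u_single < cfg.single_stay_fraction, 1, 1 + extra)
    ends = np.cumsum(counts)
    n_patients = int(np.searchsorted(ends, n_stays, side="left")) + 1
    patient_of_stay = np.repeat(np.arange(n_patients), counts[:n_patients])[:n_stays]
    return patient_of_stay


def generate_cohort(config: CohortConfig) -> list[StayRecord]:
    """Generate a synthetic cohort of ICU stays.

    Deterministic given ``config.seed``. Latent draws (severity, noise,
    excursion/missingness uniforms, outcome uniforms) are consumed in a fixed
    order that does not depend on coefficient values, so changing a coefficient
    reuses the same underlying randomness.
    """
    config.validate()
    n = config.n_stays
    m = config.obs_per_day
    rng = np.random.default_rng(config.seed)
    if n == 0:
        return []

    patient_of_stay = _assign_patients(n, config, rng)
    n_patients = int(patient_of_stay.max()) + 1

    # Patient-level demographics (shared across a patient's stays).
    age = np.clip(
        rng.normal(*config.age_params, size=n_patients), *config.age_range
    )
    male = rng.random(n_patients) < config.male_fraction
    height = np.clip(rng.normal(*config.height_params, size=n_patients), 120.0, 210.0)
    weight = np.clip(rng.normal(*config.weight_params, size=n_patients), 30.0, 260.0)

    # Stay-level latents.
    severity = rng.normal(size=n)
    n_vitals = len(VITALS)
    noise = rng.standard_normal((n, n_vitals, m))
    u_exc = rng.random((n, n_vitals, m))
    u_sign = rng.random((n, n_vitals, m))
    u_miss = rng.random((n, n_vitals, m))
    time_jitter = rng.random((n, n_vitals, m))
    u_mort = rng.random(n)
    los_noise = rng.standard_normal(n)

    pop_mean = np.array([config.vital_population_params[v][0] for v in VITALS])
    pop_sd = np.array([config.vital_population_params[v][1] for v in VITALS])
    loading = np.array([config.severity_effect[v] for v in VITALS])
    exc_prob = np.array([config.tail_excursion[v][0] for v in VITALS])
    exc_mag = np.array([config.tail_excursion[v][1] for v in VITALS])

    level = pop_mean[None, :] + loading[None, :] * severity[:, None]  # (n, 7)
    values = level[:, :, None] + pop_sd[None, :, None] * noise

    p_eff = np.clip(
        exc_prob[None, :, None]
        * np.exp(config.excursion_severity_scale * severity[:, None, None]),
        0.0,
        0.9,
    )
    excursion = u_exc < p_eff
    sign = np.where(u_sign < 0.5, -1.0, 1.0)
    values = values + excursion * sign * (exc_mag * pop_sd)[None, :, None]

    tail_burden = excursion.reshape(n, -1).mean(axis=1)

    logits = (
        config.mortality_intercept
        + config.mortality_severity_coef * severity
        + config.mortality_tailburden_coef * tail_burden
    )
    p_mort = 1.0 / (1.0 + np.exp(-logits))
    mortality = (u_mort < p_mort).astype(int)

    los = np.exp(
        config.los_log_mean
        + config.los_severity_coef * severity
        + config.los_log_sd * los_noise
    )
    los = np.clip(los, LOS_MIN_DAYS, LOS_MAX_DAYS)

    missing = u_miss < config.missing_rate
    values = np.where(missing, np.nan, values)

    # Jittered hourly grid in [0, 24).
    grid = np.arange(m)[None, None, :]
    times = (grid + time_jitter) * (24.0 / m)

    stays: list[StayRecord] = []
    for i in range(n):
        pid = int(patient_of_stay[i])
        series = {
            v: VitalObservationSeries(v, times[i, j], values[i, j])
            for j, v in enumerate(VITALS)
        }
        stays.append(
            StayRecord(
                stay_id=i + 1,
                patient_id=pid + 1,
                age=float(age[pid]),
                gender="M" if male[pid] else "F",
                height=float(height[pid]),
                weight=float(weight[pid]),
                los_days=float(los[i]),
                mortality=int(mortality[i]),
                series=series,
                tail_burden=float(tail_burden[i]),
            )
        )
    return stays


# ---------------------------------------------------------------------------
# Flat-file round trip


def cohort_to_frames(stays: Iterable[StayRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort into (stays, observations) DataFrames."""
    stay_rows = []
    obs_parts = []
    for stay in stays:
        stay_rows.append(
            {
                "stay_id": stay.stay_id,
                "patient_id": stay.patient_id,
                "age": stay.age,
                "gender": stay.gender,
                "height_cm": stay.height,
                "weight_kg": stay.weight,
                "los_days": stay.los_days,
                "mortality": stay.mortality,
            }
        )
        for v in VITALS:
            s = stay.series[v]
            if len(s) == 0:
                continue
            obs_parts.append(
                pd.DataFrame(
                    {
                        "stay_id": stay.stay_id,
                        "vital_name": v,
                        "time_hours": s.times,
                        "value": s.values,
                    }
                )
            )
    stays_df = pd.DataFrame(
        stay_rows,
        columns=[
            "stay_id",
            "patient_id",
            "age",
            "gender",
            "height_cm",
            "weight_kg",
            "los_days",
            "mortality",
        ],
    )
    if obs_parts:
        obs_df = pd.concat(obs_parts, ignore_index=True)
    else:
        obs_df = pd.DataFrame(columns=["stay_id", "vital_name", "time_hours", "value"])
    return stays_df, obs_df


class CohortParseError(ValueError):
    """Malformed cohort CSV input."""


def frames_to_cohort(stays_df: pd.DataFrame, obs_df: pd.DataFrame) -> list[StayRecord]:
    """Rebuild StayRecords from flat (stays, observations) tables."""
    required = {"stay_id", "patient_id", "age", "gender", "height_cm", "weight_kg",
                "los_days", "mortality"}
    if not required.issubset(stays_df.columns):
        missing = sorted(required - set(stays_df.columns))
        raise CohortParseError(f"stays table missing columns: {missing}")
    req_obs = {"stay_id", "vital_name", "time_hours", "value"}
    if not req_obs.issubset(obs_df.columns):
        missing = sorted(req_obs - set(obs_df.columns))
        raise CohortParseError(f"observations table missing columns: {missing}")
    bad = set(obs_df["vital_name"].unique()) - set(VITALS)
    if bad:
        raise CohortParseError(f"unknown vital name(s): {sorted(bad)}")
    if stays_df["stay_id"].duplicated().any():
        raise CohortParseError("duplicate stay_id in stays table")

    grouped: dict[tuple[int, str], pd.DataFrame] = {
        key: g for key, g in obs_df.groupby(["stay_id", "vital_name"], sort=False)
    }
    stays = []
    for row in stays_df.itertuples(index=False):
        series = {}
        for v in VITALS:
            g = grouped.get((row.stay_id, v))
            if g is None:
                series[v] = VitalObservationSeries(v, np.zeros(0), np.zeros(0))
            else:
                order = np.argsort(g["time_hours"].to_numpy(), kind="stable")
                series[v] = VitalObservationSeries(
                    v,
                    g["time_hours"].to_numpy()[order],
                    g["value"].to_numpy(dtype=float)[order],
                )
        stays.append(
            StayRecord(
                stay_id=int(row.stay_id),
                patient_id=int(row.patient_id),
                age=float(row.age),
                gender=str(row.gender),
                height=float(row.height_cm),
                weight=float(row.weight_kg),
                los_days=float(row.los_days),
                mortality=int(row.mortality),
                series=series,
            )
        )
    return stays


def write_cohort_csv(stays: Iterable[StayRecord], directory: str | Path) -> list[Path]:
    """Write `stays.csv` and `observations.csv` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stays_df, obs_df = cohort_to_frames(stays)
    stays_path = directory / "stays.csv"
    obs_path = directory / "observations.csv"
    stays_df.to_csv(stays_path, index=False, float_format="%.10g")
    obs_df.to_csv(obs_path, index=False, float_format="%.10g")
    return [stays_path, obs_path]


def read_cohort_csv(directory: str | Path) -> list[StayRecord]:
    """Read a cohort written by :func:`write_cohort_csv`.

    Empty ``value`` fields are read as missing (NaN) observations.
    """
    directory = Path(directory)
    stays_path = directory / "stays.csv"
    obs_path = directory / "observations.csv"
    for p in (stays_path, obs_path):
        if not p.exists():
            raise CohortParseError(f"missing cohort file: {p}")
    try:
        stays_df = pd.read_csv(stays_path)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise CohortParseError(f"{stays_path}: {exc}") from exc
    try:
        obs_df = pd.read_csv(
            obs_path,
            dtype={"stay_id": int, "vital_name": str},
        )
    except ValueError as exc:
        raise CohortParseError(f"{obs_path}: {exc}") from exc
    if len(obs_df):
        numeric = pd.to_numeric(obs_df["value"], errors="coerce")
        bad = numeric.isna() & obs_df["value"].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise CohortParseError(f"{obs_path}: non-numeric value at line {line}")
        obs_df["value"] = numeric
        obs_df["time_hours"] = pd.to_numeric(obs_df["time_hours"])
    return frames_to_cohort(stays_df, obs_df)
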