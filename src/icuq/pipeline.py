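"""End-to-end workflow: simulate -> prepare -> features -> outcomes -> train ->
evaluate -> report, over flat CSV/JSON artifacts.

Each stage reads and writes only documented files under the run directory, so
stages are independently runnable and testable:

* ``stays.csv`` / ``observations.csv`` — the raw cohort
* ``baseline_features.csv`` — per-stay means + demographics (+ outcomes)
* ``quantile_features.csv`` — the 21 engineered tail-quantile columns
* ``outcomes.csv`` / ``outcome_summary.json``
* ``descriptives.json`` — cohort descriptive statistics
* ``results.json`` — the 28-row experiment grid
* ``sensitivity.json`` — patient-overlap-removed rerun + age ablation
* ``manifest.json`` — config snapshot, seeds, output hashes
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .models import CLASSIFIERS, REGRESSORS, SplitSpec, ICUOutcomeModel, run_experiment_grid
from .outcomes import build_outcomes
from .prep import (
    DEFAULT_CLEANING_RULES,
    CleaningRules,
    aggregate_baseline,
    clean_stay,
    describe_cohort,
    filter_first_day,
    impute_mean,
    pearson_matrix,
)
from .quantiles import QUANTILE_FEATURES, QuantileConfig, assemble_feature_table, engineer_table
from .prep import BASELINE_PREDICTORS
from .synth import VITALS, CohortConfig, generate_cohort, read_cohort_csv, write_cohort_csv

__all__ = [
    "PipelineError",
    "RunConfig",
    "load_config",
    "stage_simulate",
    "stage_prepare",
    "stage_features",
    "stage_outcomes",
    "stage_train_evaluate",
    "run_pipeline",
    "make_fixtures",
]

log = logging.getLogger("icuq")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Parsed pipeline configuration."""

    cohort: CohortConfig
    cleaning: CleaningRules
    quantiles: QuantileConfig
    split: SplitSpec
    algorithms: tuple[str, ...] = CLASSIFIERS + REGRESSORS

    def to_dict(self) -> dict:
        return {
            "cohort": _config_snapshot(self.cohort),
            "cleaning": {
                "ranges": {k: list(v) for k, v in self.cleaning.ranges.items()},
                "drop_nonpositive": self.cleaning.drop_nonpositive,
            },
            "quantiles": dataclasses.asdict(self.quantiles),
            "split": dataclasses.asdict(self.split),
            "algorithms": list(self.algorithms),
        }


def _config_snapshot(cfg: CohortConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for key in ("vital_population_params", "severity_effect", "tail_excursion"):
        d[key] = {k: (list(v) if isinstance(v, (tuple, list)) else v)
                  for k, v in d[key].items()}
    return d


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Load a YAML run configuration; omitted keys fall back to defaults.

    ``seed`` overrides both the cohort and the experiment seed.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}

    cohort_kwargs = dict(raw.get("cohort", {}))
    for key in ("vital_population_params", "tail_excursion"):
        if key in cohort_kwargs:
            cohort_kwargs[key] = {
                k: tuple(v) for k, v in cohort_kwargs[key].items()
            }
    for key in ("age_params", "age_range", "height_params", "weight_params"):
        if key in cohort_kwargs:
            cohort_kwargs[key] = tuple(cohort_kwargs[key])
    cohort = CohortConfig(**cohort_kwargs)

    cleaning_raw = raw.get("cleaning", {})
    if "ranges" in cleaning_raw:
        ranges = {k: tuple(v) for k, v in cleaning_raw["ranges"].items()}
        missing = [v for v in VITALS if v not in ranges]
        if missing:
            raise PipelineError(
                "configure", f"cleaning range missing for vital(s): {missing}"
            )
        cleaning = CleaningRules(
            ranges=ranges,
            drop_nonpositive=cleaning_raw.get("drop_nonpositive", True),
        )
    else:
        cleaning = DEFAULT_CLEANING_RULES

    quantiles = QuantileConfig(**raw.get("quantiles", {}))
    split = SplitSpec(**raw.get("split", {}))
    algorithms = tuple(raw.get("algorithms", CLASSIFIERS + REGRESSORS))
    unknown = set(algorithms) - set(CLASSIFIERS + REGRESSORS)
    if unknown:
        raise PipelineError("configure", f"unknown algorithm(s): {sorted(unknown)}")

    if seed is not None:
        cohort = cohort.with_(seed=seed)
        split = SplitSpec(
            train_fraction=split.train_fraction,
            k_folds=split.k_folds,
            seed=seed,
            drop_patient_overlap=split.drop_patient_overlap,
        )
    return RunConfig(cohort=cohort, cleaning=cleaning, quantiles=quantiles,
                     split=split, algorithms=algorithms)


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, allow_nan=True))


def stage_simulate(config: RunConfig, out: Path) -> list[Path]:
    try:
        stays = generate_cohort(config.cohort)
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc
    paths = write_cohort_csv(stays, out)
    log.info("simulate: %d stays written", len(stays))
    return paths


def stage_prepare(config: RunConfig, out: Path) -> list[Path]:
    try:
        stays = read_cohort_csv(out)
        n_raw = len(stays)
        stays = filter_first_day(stays)
        log.info("prepare: %d/%d stays kept after LOS >= 1 day filter", len(stays), n_raw)
        stays = [clean_stay(s, config.cleaning) for s in stays]
        table = aggregate_baseline(stays)
        vital_cols = [f"{v}_mean" for v in VITALS]
        table = impute_mean(table, vital_cols + ["height", "weight"])
        descriptives = describe_cohort(table)
        try:
            corr = pearson_matrix(table, vital_cols)
            descriptives["vital_pearson"] = corr.round(6).to_dict()
        except ValueError:
            descriptives["vital_pearson"] = None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("prepare", str(exc)) from exc
    feat_path = out / "baseline_features.csv"
    table.to_csv(feat_path, index=False, float_format="%.10g")
    desc_path = out / "descriptives.json"
    _write_json(desc_path, descriptives)
    return [feat_path, desc_path]


def stage_features(config: RunConfig, out: Path) -> list[Path]:
    try:
        stays = read_cohort_csv(out)
        stays = filter_first_day(stays)
        stays = [clean_stay(s, config.cleaning) for s in stays]
        table = engineer_table(stays, config.quantiles)
        table = impute_mean(table, list(QUANTILE_FEATURES))
    except Exception as exc:
        raise PipelineError("features", str(exc)) from exc
    path = out / "quantile_features.csv"
    table.to_csv(path, index=False, float_format="%.10g")
    log.info("features: %d engineered rows (%d columns)", len(table), len(QUANTILE_FEATURES))
    return [path]


def stage_outcomes(config: RunConfig, out: Path) -> list[Path]:
    try:
        table = pd.read_csv(out / "baseline_features.csv")
        outcome_table, summary = build_outcomes(table)
    except Exception as exc:
        raise PipelineError("outcomes", str(exc)) from exc
    csv_path = out / "outcomes.csv"
    outcome_table.to_csv(csv_path, index=False, float_format="%.10g")
    json_path = out / "outcome_summary.json"
    _write_json(json_path, summary)
    log.info("outcomes: threshold %.4f days, mortality %.3f%%",
             summary["los_threshold_days"], summary["mortality_percent"])
    return [csv_path, json_path]


def _assemble_tables(out: Path) -> dict[str, pd.DataFrame]:
    baseline = pd.read_csv(out / "baseline_features.csv")
    quantile_rows = pd.read_csv(out / "quantile_features.csv")
    return {
        "baseline": assemble_feature_table(baseline, None, "baseline"),
        "quantiles": assemble_feature_table(baseline, quantile_rows, "quantiles"),
    }


def stage_train_evaluate(config: RunConfig, out: Path) -> list[Path]:
    try:
        tables = _assemble_tables(out)
        grid = run_experiment_grid(
            tables, seed=config.split.seed, split=config.split,
            algorithms=config.algorithms,
        )
        results_path = out / "results.json"
        _write_json(results_path, grid.to_dict(orient="records"))
        log.info("train/evaluate: %d result rows", len(grid))

        # Sensitivity analysis: classifiers in engineered-feature mode with
        # patient-overlapping test stays removed.
        overlap_split = SplitSpec(
            train_fraction=config.split.train_fraction,
            k_folds=config.split.k_folds,
            seed=config.split.seed,
            drop_patient_overlap=True,
        )
        cls_algs = [a for a in config.algorithms if a in CLASSIFIERS]
        sens_rows = []
        overlap_summary = None
        for target in ("mortality", "los_binary"):
            for alg in cls_algs:
                res = ICUOutcomeModel(
                    tables["quantiles"], target=target, mode="quantiles",
                    algorithm=alg, seed=config.split.seed, split=overlap_split,
                ).fit()
                row = res.to_row()
                row["patient_overlap_removed"] = True
                sens_rows.append(row)
                overlap_summary = res.overlap_summary

        # Age ablation: tuned random forest, engineered features, both binary
        # targets, with and without the age column.
        ablation_rows = []
        if "RF" in cls_algs:
            for target in ("mortality", "los_binary"):
                for drop_age in (False, True):
                    res = ICUOutcomeModel(
                        tables["quantiles"], target=target, mode="quantiles",
                        algorithm="RF", seed=config.split.seed, split=config.split,
                        drop_age=drop_age,
                    ).fit()
                    row = res.to_row()
                    row["age_included"] = not drop_age
                    ablation_rows.append(row)
        sens_path = out / "sensitivity.json"
        _write_json(sens_path, {
            "overlap": overlap_summary,
            "without_patient_overlap": sens_rows,
            "age_ablation": ablation_rows,
        })
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("train-evaluate", str(exc)) from exc
    return [results_path, sens_path]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config_path: str | Path | None,
    out: str | Path,
    seed: int | None = None,
) -> dict:
    """Execute all stages in order and write ``manifest.json``.

    The run directory must be fresh (no prior manifest); re-running never
    mutates a previous run's outputs.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    if (out / "manifest.json").exists():
        raise PipelineError("setup", f"run directory {out} already holds a manifest")
    config = load_config(config_path, seed=seed)
    started = time.time()
    outputs: list[Path] = []
    outputs += stage_simulate(config, out)
    outputs += stage_prepare(config, out)
    outputs += stage_features(config, out)
    outputs += stage_outcomes(config, out)
    outputs += stage_train_evaluate(config, out)
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "seeds": {"cohort": config.cohort.seed, "experiment": config.split.seed},
        "outputs": {p.name: _sha256(p) for p in outputs},
        "started": started,
        "finished": time.time(),
    }
    _write_json(out / "manifest.json", manifest)
    return manifest


def make_fixtures(seed: int, directory: str | Path, n_stays: int = 50) -> list[Path]:
    """Write a miniature deterministic cohort (default 50 stays) with the
    default injected severity/tail signal, for tests and smoke runs."""
    cfg = CohortConfig(n_stays=n_stays, seed=seed)
    stays = generate_cohort(cfg)
    return write_cohort_csv(stays, directory)
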