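"""Outcome construction: in-hospital mortality and median-split length of stay.

The LOS binary target splits the cohort at its own sample median — class 0
for stays at or below the median, class 1 above — which yields balanced
classes by construction on tie-free data. The threshold is always computed
from the cohort at hand, never hard-coded.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["los_threshold", "label_los_binary", "build_outcomes"]


def los_threshold(los_values: Sequence[float] | np.ndarray) -> float:
    """Sample median of the LOS values (midpoint of the central pair for even n)."""
    v = np.asarray(los_values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot take the median of an empty sample")
    if np.any(v <= 0) or not np.isfinite(v).all():
        raise ValueError("LOS values must be positive and finite")
    return float(np.median(v))


def label_los_binary(
    los_values: Sequence[float] | np.ndarray, threshold: float
) -> np.ndarray:
    """0 for LOS <= threshold (ties to class 0), 1 for LOS > threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = np.asarray(los_values, dtype=float)
    return (v > threshold).astype(int)


def build_outcomes(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-stay outcome table and a class-balance summary.

    ``table`` must carry stay_id, los_days and mortality. The LOS threshold is
    the cohort's own median.
    """
    if len(table) == 0:
        raise ValueError("cannot build outcomes for an empty cohort")
    los = table["los_days"].to_numpy(dtype=float)
    threshold = los_threshold(los)
    los_binary = label_los_binary(los, threshold)
    out = pd.DataFrame(
        {
            "stay_id": table["stay_id"].to_numpy(),
            "mortality": table["mortality"].to_numpy(dtype=int),
            "los_binary": los_binary,
            "los_days": los,
        }
    )
    summary = {
        "n_stays": int(len(out)),
        "los_threshold_days": threshold,
        "mortality_percent": round(100.0 * float(out["mortality"].mean()), 3),
        "los_class1_percent": round(100.0 * float(out["los_binary"].mean()), 3),
        "los_mean_days": float(np.mean(los)),
        "los_sd_days": float(np.std(los, ddof=1)) if len(los) > 1 else 0.0,
    }
    return out, summary
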