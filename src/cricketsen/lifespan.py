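"""Nonparametric lifespan summaries per treatment group.

"Maximum lifespan" follows the demographic convention used for these
cohorts: the median lifespan of the longest-lived 10% of a group (top
decile of size ceil(n/10)).  Confidence intervals are percentile bootstrap,
resampling within group only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .fitting import IndividualRecord

__all__ = [
    "LifespanSummary",
    "group_median",
    "bootstrap_ci",
    "max_lifespan",
    "summarize_groups",
]

log = logging.getLogger(__name__)


def group_median(lifespans: Sequence[float]) -> float:
    """Sample median (mean of the two central order statistics for even n)."""
    arr = np.asarray(lifespans, dtype=float)
    if arr.size == 0:
        raise DataError("cannot take the median of an empty group")
    return float(np.median(arr))


def max_lifespan(lifespans: Sequence[float], top_fraction: float = 0.10) -> float:
    """Median of the longest-lived ``top_fraction`` of the group.

    The top decile has ceil(n * top_fraction) members, so n = 10 uses the
    single maximum.
    """
    arr = np.sort(np.asarray(lifespans, dtype=float))
    if arr.size == 0:
        raise DataError("cannot summarise an empty group")
    k = math.ceil(arr.size * top_fraction)
    return float(np.median(arr[-k:]))


def bootstrap_ci(
    lifespans: Sequence[float],
    statistic: Callable[[np.ndarray], float] = group_median,
    reps: int = 5000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a statistic (default: the median).

    Resamples with replacement within the group; the 2.5th and 97.5th
    percentiles of the ``reps`` bootstrap statistics form the default 95%
    interval.  Reproducible for a given seed.
    """
    arr = np.asarray(lifespans, dtype=float)
    if arr.size == 0:
        raise DataError("cannot bootstrap an empty group")
    if reps < 1:
        raise DataError(f"bootstrap reps must be >= 1, got {reps}")
    if arr.size == 1:
        log.warning("group of size 1: degenerate bootstrap CI")
        return (float(arr[0]), float(arr[0]))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(reps, arr.size))
    boot = np.apply_along_axis(statistic, 1, arr[idx])
    lo, hi = np.percentile(boot, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return (float(lo), float(hi))


@dataclass(frozen=True)
class LifespanSummary:
    group: str
    n: int
    median_days: float
    ci95: tuple[float, float]
    max_median_days: float
    bootstrap_reps: int
    seed: int


def summarize_groups(
    records: Sequence[IndividualRecord],
    reps: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Median (with bootstrap 95% CI) and top-decile median lifespan per
    sex x diet x mating group, as one table."""
    frame = pd.DataFrame(
        {
            "sex": [r.sex for r in records],
            "diet": [r.diet for r in records],
            "mating": [r.mating for r in records],
            "lifespan": [r.lifespan for r in records],
        }
    )
    if frame.empty:
        raise DataError("no records supplied")
    rows = []
    root = np.random.SeedSequence(seed)
    keys = sorted(frame.groupby(["sex", "diet", "mating"]).groups)
    streams = root.spawn(len(keys))
    grouped = frame.groupby(["sex", "diet", "mating"])
    for (key, stream) in zip(keys, streams):
        values = grouped.get_group(key)["lifespan"].to_numpy()
        label = f"{key[0]}-{key[1]}{'V' if key[2] == 'virgin' else 'M'}"
        ci = bootstrap_ci(values, reps=reps, seed=np.random.default_rng(stream))
        rows.append(
            {
                "group": label,
                "sex": key[0],
                "diet": key[1],
                "mating": key[2],
                "n": values.size,
                "median": group_median(values),
                "ci_low": ci[0],
                "ci_high": ci[1],
                "max_median": max_lifespan(values),
            }
        )
    return pd.DataFrame(rows)
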