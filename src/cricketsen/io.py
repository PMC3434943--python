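"""CSV readers/writers and the JSON pipeline report.

Cohort CSV: columns id, sex, diet, mating, lifespan_days[, mass_g,
pronotum_mm]; header required, UTF-8.  Calling CSV: columns id, age_days,
calling_s.  Schema violations are collected and reported together, never
silently dropped; unknown extra columns ride along untouched.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import CALLING_MAX_S
from .errors import DataError
from .fitting import DIETS, MATINGS, SEXES, IndividualRecord

__all__ = [
    "read_cohort",
    "read_calling",
    "write_cohort",
    "write_calling",
    "cohort_to_records",
    "records_to_frame",
    "join_calling",
    "write_report",
]

_COHORT_REQUIRED = ("id", "sex", "diet", "mating", "lifespan_days")
_CALLING_REQUIRED = ("id", "age_days", "calling_s")


def _read_csv(path, required: Sequence[str], label: str) -> pd.DataFrame:
    frame = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DataError(f"{label} file {path}: missing required columns {missing}")
    return frame


def _validate_cohort_frame(frame: pd.DataFrame, label: str = "cohort") -> None:
    problems: list[str] = []
    dup = frame["id"][frame["id"].duplicated()]
    if len(dup):
        problems.append(f"duplicated id values: {sorted(set(dup))[:5]}")
    for column, levels in (("sex", SEXES), ("diet", DIETS), ("mating", MATINGS)):
        bad = ~frame[column].isin(levels)
        if bad.any():
            rows = frame.index[bad].tolist()[:5]
            problems.append(
                f"column {column!r}: invalid level(s) {sorted(set(frame.loc[bad, column]))} "
                f"in row(s) {rows}; allowed {list(levels)}"
            )
    lifespan = pd.to_numeric(frame["lifespan_days"], errors="coerce")
    bad = ~(lifespan > 0) | ~np.isfinite(lifespan)
    if bad.any():
        rows = frame.index[bad].tolist()[:5]
        problems.append(f"column 'lifespan_days': non-positive or non-numeric in row(s) {rows}")
    if problems:
        raise DataError(f"{label} validation failed: " + "; ".join(problems))


def read_cohort(path) -> list[IndividualRecord]:
    """Read and validate a cohort CSV into individual records."""
    frame = _read_csv(path, _COHORT_REQUIRED, "cohort")
    return cohort_to_records(frame)


def cohort_to_records(frame: pd.DataFrame) -> list[IndividualRecord]:
    _validate_cohort_frame(frame)
    def opt(row, name):
        value = getattr(row, name, None)
        return None if value is None or pd.isna(value) else float(value)
    return [
        IndividualRecord(
            id=str(row.id),
            sex=row.sex,
            diet=row.diet,
            mating=row.mating,
            lifespan=float(row.lifespan_days),
            mass_g=opt(row, "mass_g"),
            pronotum_mm=opt(row, "pronotum_mm"),
        )
        for row in frame.itertuples(index=False)
    ]


def records_to_frame(records: Sequence[IndividualRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "sex": [r.sex for r in records],
            "diet": [r.diet for r in records],
            "mating": [r.mating for r in records],
            "lifespan_days": [r.lifespan for r in records],
            "mass_g": [r.mass_g for r in records],
            "pronotum_mm": [r.pronotum_mm for r in records],
        }
    )


def read_calling(path) -> pd.DataFrame:
    """Read and validate a calling CSV (one row per male per night)."""
    frame = _read_csv(path, _CALLING_REQUIRED, "calling")
    problems = []
    age = pd.to_numeric(frame["age_days"], errors="coerce")
    if (~np.isfinite(age) | (age < 0)).any():
        rows = frame.index[~np.isfinite(age) | (age < 0)].tolist()[:5]
        problems.append(f"column 'age_days': negative or non-numeric in row(s) {rows}")
    sec = pd.to_numeric(frame["calling_s"], errors="coerce")
    bad = ~np.isfinite(sec) | (sec < 0) | (sec > CALLING_MAX_S)
    if bad.any():
        rows = frame.index[bad].tolist()[:5]
        problems.append(
            f"column 'calling_s': outside [0, {CALLING_MAX_S:.0f}] or non-numeric "
            f"in row(s) {rows}"
        )
    if problems:
        raise DataError("calling validation failed: " + "; ".join(problems))
    return frame


def join_calling(cohort: pd.DataFrame, calling: pd.DataFrame) -> pd.DataFrame:
    """Join calling observations to their cohort rows on id.

    Produces the modelling frame (id, diet, mating, age, lifespan,
    calling_s).  A calling id with no cohort record is an error.
    """
    orphan = set(calling["id"]) - set(cohort["id"])
    if orphan:
        raise DataError(f"calling ids with no cohort record: {sorted(orphan)[:5]}")
    merged = calling.merge(
        cohort[["id", "diet", "mating", "lifespan_days"]], on="id", how="left"
    )
    return merged.rename(columns={"age_days": "age", "lifespan_days": "lifespan"})


def write_cohort(records_or_frame, path) -> None:
    frame = (
        records_or_frame
        if isinstance(records_or_frame, pd.DataFrame)
        else records_to_frame(records_or_frame)
    )
    # %.17g keeps the write -> read round trip lossless for doubles
    frame.to_csv(path, index=False, float_format="%.17g")


def write_calling(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format="%.17g")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "to_dict"):
            return obj.to_dict()
        return super().default(obj)


def config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, cls=_NumpyEncoder).encode()
    ).hexdigest()[:12]


def write_report(report: dict, path) -> None:
    """Write a pipeline report as JSON (data frames are dropped, numbers
    and tables kept)."""
    payload = {k: v for k, v in report.items() if k != "data"}
    Path(path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder))
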