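"""Synthetic cohort and calling-effort experiments.

The generator reproduces the 2 x 2 x 2 cricket study design: two sexes,
two diets (C: protein:carbohydrate 9.33:74.66, a 1:8 ratio; P: 42:42,
1:1 — both 84% protein + carbohydrate, remainder cellulose), and two
mating treatments (virgin vs mated weekly).  Defaults follow the study's
printed design: per-cell sample sizes (males CV=82, CM=76, PV=72, PM=70;
females CV=71, CM=76, PV=61, PM=67), per-cell Gompertz mortality
parameters for death times, and the best-fit fixed-effect coefficients of
the calling-effort model for male nightly calling, recorded from adult
age 4 every 5 days until death.

A master seed spawns independent sub-streams for death times, random
intercepts and residuals, so toggling one stream never shifts another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .battery import run_battery, sex_lrt
from .calling import TABLE_TERMS, CALLING_MAX_S, build_design, compare_calling_models
from .errors import ConfigurationError
from .hazards import HazardSpec, simulate_death_times
from .lifespan import summarize_groups

__all__ = [
    "DEFAULT_CELL_SIZES",
    "DEFAULT_HAZARDS",
    "DEFAULT_CALLING_COEFS",
    "ExperimentConfig",
    "validate_config",
    "generate_experiment",
    "end_to_end",
]

Cell = tuple[str, str, str]  # (sex, diet, mating)

#: printed per-cell sample sizes of the study design
DEFAULT_CELL_SIZES: dict[Cell, int] = {
    ("male", "C", "virgin"): 82,
    ("male", "C", "mated"): 76,
    ("male", "P", "virgin"): 72,
    ("male", "P", "mated"): 70,
    ("female", "C", "virgin"): 71,
    ("female", "C", "mated"): 76,
    ("female", "P", "virgin"): 61,
    ("female", "P", "mated"): 67,
}

#: per-cell Gompertz estimates (alpha, beta) from the separate-cell fits
DEFAULT_HAZARDS: dict[Cell, HazardSpec] = {
    ("male", "C", "virgin"): HazardSpec("gompertz", {"alpha": 0.0101, "beta": 0.0264}),
    ("male", "C", "mated"): HazardSpec("gompertz", {"alpha": 0.0065, "beta": 0.0406}),
    ("male", "P", "virgin"): HazardSpec("gompertz", {"alpha": 0.0073, "beta": 0.0280}),
    ("male", "P", "mated"): HazardSpec("gompertz", {"alpha": 0.0059, "beta": 0.0299}),
    ("female", "C", "virgin"): HazardSpec("gompertz", {"alpha": 0.0078, "beta": 0.0417}),
    ("female", "C", "mated"): HazardSpec("gompertz", {"alpha": 0.0075, "beta": 0.0482}),
    ("female", "P", "virgin"): HazardSpec("gompertz", {"alpha": 0.0029, "beta": 0.0418}),
    ("female", "P", "mated"): HazardSpec("gompertz", {"alpha": 0.0041, "beta": 0.0423}),
}

#: best-fit fixed effects of the calling model (seconds, seconds/day^k).
#: The intercept is not separately reported for the best-fit model and
#: defaults to 0; it shifts every prediction equally and does not affect
#: contrast or slope recovery.
DEFAULT_CALLING_COEFS: dict[str, float] = {
    "intercept": 0.0,
    "diet": 1299.3,
    "mating": 1059.1,
    "age": 95.4,
    "lifespan": 78.3,
    "age2": -3.2,
    "lifespan2": -1.0,
    "diet:age": -123.6,
    "diet:age2": 1.4,
    "age:lifespan": 2.4,
}

#: diet compositions, percent of dry mass
DEFAULT_DIETS: dict[str, dict[str, float]] = {
    "C": {"protein": 9.33, "carbohydrate": 74.66},
    "P": {"protein": 42.0, "carbohydrate": 42.0},
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Full parameterisation of one synthetic experiment."""

    cell_sizes: Mapping[Cell, int] = field(default_factory=lambda: dict(DEFAULT_CELL_SIZES))
    hazards: Mapping[Cell, HazardSpec] = field(default_factory=lambda: dict(DEFAULT_HAZARDS))
    diets: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: dict(DEFAULT_DIETS))
    calling_coefs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CALLING_COEFS)
    )
    sigma_u: float = 1500.0  # between-male SD of the random intercept (s)
    sigma_e: float = 3000.0  # nightly residual SD (s)
    first_age: int = 4       # first calling observation (days)
    interval: int = 5        # days between observations
    daily_rounding: bool = False
    clip_calling: bool = False
    seed: int = 0

    def derived_pc_ratio(self, diet: str) -> float:
        comp = self.diets[diet]
        return comp["carbohydrate"] / comp["protein"]


def validate_config(config: ExperimentConfig) -> ExperimentConfig:
    """Check design invariants and return the (normalised) config.

    Each diet's protein + carbohydrate must sum to 84% (within 0.05), cell
    sizes must be non-negative, the calling schedule interval at least one
    day, and variance components admissible.
    """
    for cell, size in config.cell_sizes.items():
        sex, diet, mating = cell
        if sex not in ("male", "female") or diet not in config.diets or mating not in (
            "virgin", "mated",
        ):
            raise ConfigurationError(f"cell_sizes[{cell}]: unknown factor level")
        if size < 0:
            raise ConfigurationError(f"cell_sizes[{cell}]: size must be >= 0, got {size}")
        if size > 0 and cell not in config.hazards:
            raise ConfigurationError(f"hazards[{cell}]: missing hazard for populated cell")
    for name, comp in config.diets.items():
        total = comp["protein"] + comp["carbohydrate"]
        if abs(total - 84.0) > 0.05:
            raise ConfigurationError(
                f"diets[{name}]: protein + carbohydrate must sum to 84% "
                f"(within 0.05), got {total}"
            )
    if config.interval < 1:
        raise ConfigurationError(f"interval: must be >= 1 day, got {config.interval}")
    if config.first_age < 0:
        raise ConfigurationError("first_age: must be >= 0")
    if config.sigma_u < 0 or config.sigma_e <= 0:
        raise ConfigurationError("sigma_u must be >= 0 and sigma_e > 0")
    if config.seed is None:
        raise ConfigurationError("seed: a master seed is required")
    unknown = set(config.calling_coefs) - set(TABLE_TERMS)
    if unknown:
        raise ConfigurationError(f"calling_coefs: unknown terms {sorted(unknown)}")
    return config


_CELL_ORDER: list[Cell] = [
    (sex, diet, mating)
    for sex in ("male", "female")
    for diet in ("C", "P")
    for mating in ("virgin", "mated")
]


def generate_experiment(
    config: ExperimentConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one experiment: a cohort table and a calling table.

    Death times are drawn per cell from its hazard (optionally rounded up
    to whole days, emulating daily survival checks).  Each male gets
    calling observations at ages ``first_age``, ``first_age + interval``,
    ... strictly below its lifespan, generated from the linear-Gaussian
    calling model with its own random intercept.  Deterministic per seed;
    group counts equal the configured sizes exactly.
    """
    config = validate_config(config or ExperimentConfig())
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    s_death, s_intercept, s_resid = ss.spawn(3)
    rng_death = np.random.default_rng(s_death)
    rng_u = np.random.default_rng(s_intercept)
    rng_e = np.random.default_rng(s_resid)

    rows = []
    for cell in _CELL_ORDER:
        n = config.cell_sizes.get(cell, 0)
        if n == 0:
            continue
        sex, diet, mating = cell
        times = simulate_death_times(config.hazards[cell], n, rng_death)
        if config.daily_rounding:
            times = np.maximum(np.ceil(times), 1.0)
        tag = f"{sex[0]}{diet}{'V' if mating == 'virgin' else 'M'}"
        for i, t in enumerate(times):
            rows.append(
                {"id": f"{tag}-{i:04d}", "sex": sex, "diet": diet,
                 "mating": mating, "lifespan_days": float(t)}
            )
    cohort = pd.DataFrame(rows)

    males = cohort[cohort["sex"] == "male"]
    calling = _generate_calling(males, config, rng_u, rng_e)
    return cohort, calling


def _generate_calling(
    males: pd.DataFrame,
    config: ExperimentConfig,
    rng_u: np.random.Generator,
    rng_e: np.random.Generator,
) -> pd.DataFrame:
    intercepts = rng_u.normal(0.0, config.sigma_u, size=len(males))
    obs_rows = []
    for (row, u) in zip(males.itertuples(index=False), intercepts):
        ages = np.arange(config.first_age, row.lifespan_days, config.interval, dtype=float)
        for a in ages:
            obs_rows.append(
                {"id": row.id, "diet": row.diet, "mating": row.mating,
                 "age": a, "lifespan": row.lifespan_days, "u": u}
            )
    if not obs_rows:
        return pd.DataFrame(columns=["id", "age", "calling_s"])
    frame = pd.DataFrame(obs_rows)
    frame["calling_s"] = 0.0  # placeholder so build_design accepts the frame
    terms = tuple(t for t in TABLE_TERMS if t in config.calling_coefs)
    X, _, _ = build_design(frame, terms)
    beta = np.array([config.calling_coefs[t] for t in terms])
    mean = X @ beta + frame["u"].to_numpy()
    y = mean + rng_e.normal(0.0, config.sigma_e, size=len(frame))
    if config.clip_calling:
        y = np.clip(y, 0.0, CALLING_MAX_S)
    out = frame[["id", "age", "calling_s"]].copy()
    out["calling_s"] = y
    out = out.rename(columns={"age": "age_days"})
    return out


def end_to_end(config: ExperimentConfig | None = None, seed: int | None = None) -> dict:
    """Run the full pipeline on one synthetic experiment.

    generate -> per-sex model battery -> pooled-vs-sexed likelihood-ratio
    test -> lifespan table -> calling-model comparison, returned as one
    JSON-serialisable report (plus the two data frames under "data").
    """
    from .io import cohort_to_records, join_calling  # local import, avoids cycle

    config = validate_config(config or ExperimentConfig())
    master = config.seed if seed is None else seed
    cohort, calling = generate_experiment(config, master)
    records = cohort_to_records(cohort)

    report: dict = {"seed": master, "stages": {}}
    try:
        batteries = {}
        for sex in ("male", "female"):
            subset = [r for r in records if r.sex == sex]
            if subset:
                batteries[sex] = run_battery(subset)
        report["stages"]["battery"] = {
            sex: b.to_dict() for sex, b in batteries.items()
        }
    except Exception as exc:
        raise RuntimeError(f"battery stage failed: {exc}") from exc
    try:
        if any(r.sex == "male" for r in records) and any(r.sex == "female" for r in records):
            lrt = sex_lrt(records)
            report["stages"]["sex_lrt"] = {
                k: lrt[k] for k in ("statistic", "df", "p", "loglik_sexed", "loglik_pooled")
            }
    except Exception as exc:
        raise RuntimeError(f"sex-LRT stage failed: {exc}") from exc
    try:
        table = summarize_groups(records, seed=master)
        report["stages"]["lifespan"] = table.to_dict(orient="records")
    except Exception as exc:
        raise RuntimeError(f"lifespan stage failed: {exc}") from exc
    try:
        if len(calling):
            joined = join_calling(cohort, calling)
            candidates = [
                list(TABLE_TERMS),
                [t for t in TABLE_TERMS if not t.startswith("diet:")],
                ["intercept", "mating", "age", "age2", "lifespan", "lifespan2",
                 "age:lifespan"],
                ["intercept", "age", "age2"],
            ]
            comparison = compare_calling_models(candidates, joined)
            report["stages"]["calling"] = comparison.to_dict(orient="records")
    except Exception as exc:
        raise RuntimeError(f"calling stage failed: {exc}") from exc
    report["data"] = {"cohort": cohort, "calling": calling}
    return report


def config_with(config: ExperimentConfig | None = None, **overrides) -> ExperimentConfig:
    """Convenience: a copy of (default) config with fields replaced."""
    return replace(config or ExperimentConfig(), **overrides)
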