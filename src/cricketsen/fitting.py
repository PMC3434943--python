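"""Maximum-likelihood fitting of hazard models to individual death times.

Treatment structure
-------------------
Every animal sits in one cell of a diet (C vs P) by mating (mated vs virgin)
design.  A :class:`ModelStructure` names the hazard family and says which
treatment terms act on the level parameter ("alpha": Gompertz alpha, Weibull
a, or the constant hazard) and which on the shape parameter ("beta":
Gompertz beta or Weibull b).  Effects are multiplicative on the natural
scale — additive on the log working scale on which all optimisation runs —
so parameters stay positive by construction.  Baseline levels are diet C and
mated; the reported effects are the diet-P and virgin contrasts.

Death times are treated as exact continuous ages.  All animals are followed
to death, so there are no censoring terms in the likelihood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from .errors import ConfigurationError, DataError, DomainError, UsageError
from .hazards import FAMILIES, HazardSpec, log_density

__all__ = [
    "IndividualRecord",
    "ModelStructure",
    "FitResult",
    "neg_log_likelihood",
    "fit_mortality",
    "confint",
]

log = logging.getLogger(__name__)

SEXES = ("male", "female")
DIETS = ("C", "P")
MATINGS = ("mated", "virgin")

#: treatment terms, in canonical order; "diet:mated" is the interaction
TERMS = ("diet", "mated", "diet:mated")

_CHI2_95_DF1 = stats.chi2.ppf(0.95, 1)  # 3.8415


@dataclass(frozen=True)
class IndividualRecord:
    """One animal: treatment factors plus adult lifespan in days.

    ``mass_g`` and ``pronotum_mm`` are carried through I/O but never enter a
    likelihood.
    """

    id: str
    sex: str
    diet: str
    mating: str
    lifespan: float
    mass_g: float | None = None
    pronotum_mm: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DataError(f"record {self.id!r}: sex must be one of {SEXES}, got {self.sex!r}")
        if self.diet not in DIETS:
            raise DataError(f"record {self.id!r}: diet must be one of {DIETS}, got {self.diet!r}")
        if self.mating not in MATINGS:
            raise DataError(
                f"record {self.id!r}: mating must be one of {MATINGS}, got {self.mating!r}"
            )
        if not (self.lifespan > 0 and math.isfinite(self.lifespan)):
            raise DataError(f"record {self.id!r}: lifespan must be finite and > 0")


def _validate_terms(terms: Iterable[str], which: str) -> tuple[str, ...]:
    tset = tuple(t for t in TERMS if t in set(terms))
    unknown = set(terms) - set(TERMS)
    if unknown:
        raise ConfigurationError(f"unknown {which} terms {sorted(unknown)}; allowed: {TERMS}")
    if "diet:mated" in tset and not {"diet", "mated"} <= set(tset):
        raise ConfigurationError(
            f"{which} terms {sorted(terms)}: the diet:mated interaction requires "
            "both main effects (hierarchical marginality)"
        )
    return tset


@dataclass(frozen=True)
class ModelStructure:
    """Which treatment factors act on which hazard parameter."""

    family: str = "gompertz"
    alpha_terms: tuple[str, ...] = ()
    beta_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        object.__setattr__(self, "alpha_terms", _validate_terms(self.alpha_terms, "alpha"))
        object.__setattr__(self, "beta_terms", _validate_terms(self.beta_terms, "beta"))
        if self.family == "constant" and self.beta_terms:
            raise ConfigurationError("the constant-hazard family has no beta parameter")

    # --- parameter bookkeeping -------------------------------------------
    @property
    def shape_param(self) -> str | None:
        """Name of the family's shape parameter, if any."""
        return {"constant": None, "weibull": "b"}.get(self.family, "beta")

    @property
    def level_param(self) -> str:
        return "a" if self.family == "weibull" else "alpha"

    @property
    def aux_params(self) -> tuple[str, ...]:
        """Family parameters shared across cells (Makeham c, logistic s)."""
        used = {self.level_param, self.shape_param}
        return tuple(n for n in FAMILIES[self.family] if n not in used)

    def param_names(self) -> list[str]:
        names = [self.level_param]
        names += [f"{self.level_param}:{t}" for t in self.alpha_terms]
        if self.shape_param is not None:
            names.append(self.shape_param)
            names += [f"{self.shape_param}:{t}" for t in self.beta_terms]
        names += list(self.aux_params)
        return names

    @property
    def n_params(self) -> int:
        return len(self.param_names())

    @property
    def label(self) -> str:
        if self.family == "constant":
            return "constant"
        a = "+".join(self.alpha_terms) or "1"
        b = "+".join(self.beta_terms) or "1"
        return f"{self.family} alpha~{a} beta~{b}"

    def embed_working(self, other: "ModelStructure", w: np.ndarray) -> np.ndarray:
        """Embed a nested structure's working vector into this layout,
        zero-filling the terms ``other`` lacks.  Used for warm starts."""
        if other.family != self.family:
            raise UsageError("can only embed a fit of the same family")
        src = dict(zip(other.param_names(), np.asarray(w, dtype=float)))
        return np.array([src.get(name, 0.0) for name in self.param_names()])

    def cell_spec(self, diet: str, mating: str, working: np.ndarray) -> HazardSpec:
        """Hazard spec for one treatment cell from the working-scale vector."""
        ind = {"diet": diet == "P", "mated": mating == "virgin"}
        ind["diet:mated"] = ind["diet"] and ind["mated"]
        i = 0
        w_level = working[i]
        i += 1
        for t in self.alpha_terms:
            if ind[t]:
                w_level += working[i]
            i += 1
        params = {self.level_param: math.exp(w_level)}
        if self.shape_param is not None:
            w_shape = working[i]
            i += 1
            for t in self.beta_terms:
                if ind[t]:
                    w_shape += working[i]
                i += 1
            params[self.shape_param] = math.exp(w_shape)
        for name in self.aux_params:
            params[name] = math.exp(working[i])
            i += 1
        return HazardSpec(self.family, params)


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    structure: ModelStructure
    estimates: dict[str, float]
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    ci95: dict[str, tuple[float, float]] | None = None
    ci_method: str | None = None
    working: np.ndarray | None = field(default=None, repr=False)
    _records: tuple[IndividualRecord, ...] | None = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def to_dict(self) -> dict:
        out = {
            "family": self.structure.family,
            "alpha_terms": list(self.structure.alpha_terms),
            "beta_terms": list(self.structure.beta_terms),
            "label": self.structure.label,
            "estimates": self.estimates,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "converged": self.converged,
        }
        if self.ci95 is not None:
            out["ci95"] = {k: list(v) for k, v in self.ci95.items()}
            out["ci_method"] = self.ci_method
        return out


# --------------------------------------------------------------------------
# likelihood


def _group_cells(records: Sequence[IndividualRecord]) -> dict[tuple[str, str], np.ndarray]:
    cells: dict[tuple[str, str], list[float]] = {}
    for r in records:
        cells.setdefault((r.diet, r.mating), []).append(r.lifespan)
    # sorted keys and sorted times make every sum order-independent, so
    # permuting the input records changes no output bit
    return {k: np.sort(np.asarray(cells[k], dtype=float)) for k in sorted(cells)}


def neg_log_likelihood(
    records: Sequence[IndividualRecord] | dict[tuple[str, str], np.ndarray],
    structure: ModelStructure,
    params: np.ndarray,
) -> float:
    """Negative log-likelihood at a working-scale (log) parameter vector.

    ``records`` may be pre-grouped (diet, mating) -> lifespans for speed in
    tight optimisation loops.
    """
    params = np.asarray(params, dtype=float)
    if params.shape != (structure.n_params,):
        raise ConfigurationError(
            f"structure {structure.label!r} needs {structure.n_params} parameters, "
            f"got vector of length {len(params)}"
        )
    cells = records if isinstance(records, dict) else _group_cells(records)
    if not cells:
        raise DataError("no records supplied")
    total = 0.0
    for (diet, mating), times in cells.items():
        try:
            spec = structure.cell_spec(diet, mating, params)
        except (DomainError, OverflowError):
            return np.inf
        ld = log_density(spec, times)
        if not np.all(np.isfinite(ld)):
            return np.inf
        total += float(np.sum(ld))
    return -total


def _make_objective(cells: dict, structure: ModelStructure):
    """Objective closure for the optimiser.

    For the Gompertz and constant families (the battery's workhorses) the
    per-cell log-likelihood has the closed form
    n*log(alpha) + beta*sum(t) + (alpha/beta)*(n - sum(exp(beta*t))),
    evaluated from precomputed per-cell statistics; other families go
    through the generic density path.
    """
    # a large finite penalty keeps gradient-based polishing well-behaved
    # where the likelihood is undefined
    big = 1e12
    if structure.family not in ("gompertz", "constant"):
        return lambda w: min(neg_log_likelihood(cells, structure, w), big)

    n_a = len(structure.alpha_terms)
    prepared = []
    for (diet, mating), times in cells.items():
        ind = {"diet": diet == "P", "mated": mating == "virgin"}
        ind["diet:mated"] = ind["diet"] and ind["mated"]
        a_mask = np.array([ind[t] for t in structure.alpha_terms], dtype=float)
        b_mask = np.array([ind[t] for t in structure.beta_terms], dtype=float)
        prepared.append((a_mask, b_mask, times, times.size, float(np.sum(times))))

    if structure.family == "constant":
        def objective(w: np.ndarray) -> float:
            total = 0.0
            for a_mask, _, _, n, sum_t in prepared:
                log_a = w[0] + float(a_mask @ w[1 : 1 + n_a]) if n_a else w[0]
                total += n * log_a - math.exp(log_a) * sum_t
            return -total
        return objective

    def objective(w: np.ndarray) -> float:
        total = 0.0
        for a_mask, b_mask, times, n, sum_t in prepared:
            log_a = w[0] + (float(a_mask @ w[1 : 1 + n_a]) if n_a else 0.0)
            log_b = w[1 + n_a] + (
                float(b_mask @ w[2 + n_a :]) if b_mask.size else 0.0
            )
            if log_a > 50 or log_b > 50 or log_a < -200 or log_b < -200:
                return big
            alpha, beta = math.exp(log_a), math.exp(log_b)
            with np.errstate(over="ignore"):
                e_sum = float(np.sum(np.exp(beta * times)))
            if not math.isfinite(e_sum):
                return big
            total += n * log_a + beta * sum_t + (alpha / beta) * (n - e_sum)
        return -total

    return objective


def _check_cells(cells: dict, structure: ModelStructure) -> None:
    for (diet, mating), times in cells.items():
        if len(times) < 2:
            raise DataError(
                f"treatment cell diet={diet}, mating={mating} has {len(times)} "
                "death(s); at least 2 are required"
            )


def _start_vector(cells: dict, structure: ModelStructure) -> np.ndarray:
    """Moment-flavoured starting values on the working (log) scale."""
    alltimes = np.concatenate(list(cells.values()))
    mean_t = float(np.mean(alltimes))
    start = {"alpha": math.log(0.5 / mean_t), "beta": math.log(0.04)}
    w = [start["alpha"]] + [0.0] * len(structure.alpha_terms)
    if structure.family == "weibull":
        w = [math.log(1.0 / mean_t)] + [0.0] * len(structure.alpha_terms)
        w += [0.0] + [0.0] * len(structure.beta_terms)  # b = 1
    elif structure.shape_param is not None:
        w += [start["beta"]] + [0.0] * len(structure.beta_terms)
    for name in structure.aux_params:
        w.append(math.log(1e-3) if name == "c" else math.log(0.3))
    return np.asarray(w, dtype=float)


def fit_mortality(
    records: Sequence[IndividualRecord],
    structure: ModelStructure,
    *,
    n_restarts: int = 5,
    restart_seed: int = 0,
    jitter_sd: float = 0.5,
    tol: float = 1e-8,
    ci: str = "none",
    extra_starts: Sequence[np.ndarray] = (),
) -> FitResult:
    """Fit a hazard model by maximum likelihood on the log-parameter scale.

    A Nelder-Mead pass from a moment-based start is polished with BFGS;
    ``n_restarts`` jittered restarts (fixed ``restart_seed``) guard against
    local optima, and the best optimum wins.  Results are deterministic for
    a given dataset and configuration, and invariant to record order.
    ``extra_starts`` lets callers add warm starts (e.g. a nested fit's
    optimum embedded with zero effects).

    ``ci`` is "none", "profile" or "wald"; see :func:`confint`.
    """
    records = tuple(records)
    cells = _group_cells(records)
    if not cells:
        raise DataError("no records supplied")
    _check_cells(cells, structure)

    objective = _make_objective(cells, structure)

    base = _start_vector(cells, structure)
    rng = np.random.default_rng(restart_seed)
    starts = [base] + [np.asarray(s, dtype=float) for s in extra_starts]
    starts += [base + rng.normal(0.0, jitter_sd, size=base.size) for _ in range(n_restarts)]

    best = None
    any_ok = False
    for w0 in starts:
        try:
            nm = optimize.minimize(
                objective, w0, method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": tol, "maxiter": 2000},
            )
            polish = optimize.minimize(objective, nm.x, method="BFGS",
                                       options={"gtol": 1e-7})
            cand = polish if polish.fun <= nm.fun else nm
        except (ValueError, FloatingPointError):  # pragma: no cover - defensive
            continue
        if not np.isfinite(cand.fun):
            continue
        any_ok = any_ok or bool(cand.success or nm.success)
        if best is None or cand.fun < best.fun:
            best = cand

    if best is None:
        log.warning("fit of %s failed to produce a finite optimum", structure.label)
        return FitResult(structure, {}, -np.inf, structure.n_params, len(records),
                         converged=False, _records=records)

    names = structure.param_names()
    estimates = {n: math.exp(w) for n, w in zip(names, best.x)}
    result = FitResult(
        structure=structure,
        estimates=estimates,
        loglik=-float(best.fun),
        n_params=structure.n_params,
        n_obs=len(records),
        converged=bool(any_ok and np.isfinite(best.fun)),
        working=np.asarray(best.x, dtype=float),
        _records=records,
    )
    if ci != "none":
        result = confint(result, method=ci)
    return result


# --------------------------------------------------------------------------
# confidence intervals


def _wald_se(fit: FitResult) -> np.ndarray:
    cells = _group_cells(fit._records)
    f = lambda w: neg_log_likelihood(cells, fit.structure, w)
    hess = approx_hess1(fit.working, f)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(fit.working.size, np.nan)
    return se


def _make_profile_dev(objective, w_hat, nll_min, j):
    """Profile deviance as a function of working parameter j.

    Nuisance parameters are re-optimised at every evaluation, warm-started
    from the previous inner solution (1-D inner problems use Brent).
    """
    free = [i for i in range(w_hat.size) if i != j]
    state = {"x": w_hat[free] if free else None}

    def profile_dev(wj: float) -> float:
        if not free:
            return 2.0 * (objective(np.array([wj])) - nll_min)
        def inner(wf):
            full = np.empty(w_hat.size)
            full[j] = wj
            full[free] = np.atleast_1d(wf)
            return objective(full)
        if len(free) == 1:
            x0 = float(state["x"][0])
            res = optimize.minimize_scalar(
                inner, bounds=(x0 - 10.0, x0 + 10.0), method="bounded",
                options={"xatol": 1e-8},
            )
            fun, x = res.fun, np.atleast_1d(res.x)
        else:
            res = optimize.minimize(inner, state["x"], method="Nelder-Mead",
                                    options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000})
            fun, x = res.fun, res.x
        if x is not None and np.all(np.isfinite(x)):
            state["x"] = x
        return 2.0 * (fun - nll_min)

    return profile_dev


def _gompertz_profile_dev(times: np.ndarray, w_hat, nll_min, j):
    """Fast profile deviance for the plain two-parameter Gompertz fit.

    Profiling beta (j = 1) uses the closed-form conditional MLE
    alpha(beta) = n*beta / (sum(exp(beta*t)) - n); profiling alpha falls
    back to a 1-D Brent search over log beta.
    """
    n = times.size
    sum_t = float(np.sum(times))

    def nll(log_a: float, log_b: float) -> float:
        a, b = math.exp(log_a), math.exp(log_b)
        e = np.exp(b * times)
        return -(n * log_a + b * sum_t + (a / b) * (n - float(np.sum(e))))

    if j == 1:  # beta profiled, alpha closed form
        def profile_dev(log_b: float) -> float:
            b = math.exp(log_b)
            denom = float(np.sum(np.expm1(b * times)))
            if denom <= 0:
                return np.inf
            log_a = math.log(n * b / denom)
            return 2.0 * (nll(log_a, log_b) - nll_min)
    else:
        state = {"x": float(w_hat[1])}

        def profile_dev(log_a: float) -> float:
            res = optimize.minimize_scalar(
                lambda lb: nll(log_a, lb),
                bounds=(state["x"] - 8.0, state["x"] + 8.0),
                method="bounded", options={"xatol": 1e-9},
            )
            if np.isfinite(res.x):
                state["x"] = float(res.x)
            return 2.0 * (res.fun - nll_min)

    return profile_dev


def _profile_bound(profile_dev, w_hat, j, se_j, side) -> float | None:
    """One side of the profile-likelihood CI for working parameter j.

    Walks outward in units of the Wald SE until the profile deviance crosses
    the chi-square(1) 95% cutoff, then solves the crossing by Brent's method.
    Returns the bound on the working scale, or None if no bracket is found.
    """
    step = se_j if np.isfinite(se_j) and se_j > 0 else 0.25
    lo = w_hat[j]
    for k in range(1, 40):
        hi = w_hat[j] + side * step * (1.6 ** k)
        dev = profile_dev(hi)
        if not np.isfinite(dev):
            return None
        if dev >= _CHI2_95_DF1:
            break
        lo = hi
    else:
        return None
    f = lambda wj: profile_dev(wj) - _CHI2_95_DF1
    a, b = (lo, hi) if lo < hi else (hi, lo)
    try:
        return float(optimize.brentq(f, a, b, xtol=1e-6))
    except ValueError:
        return None


def confint(fit: FitResult, method: str = "profile") -> FitResult:
    """Attach 95% confidence intervals to a converged fit.

    ``profile`` (default) inverts the likelihood-ratio statistic on the
    working scale; if a profile bound cannot be bracketed the parameter
    falls back to a Wald interval (log scale, exponentiated) with a logged
    warning.  Only estimated parameters get intervals.
    """
    if method not in ("profile", "wald"):
        raise UsageError(f"unknown CI method {method!r}")
    if not fit.converged or fit.working is None or fit._records is None:
        raise UsageError("confidence intervals require a converged fit with attached data")

    cells = _group_cells(fit._records)
    objective = lambda w: neg_log_likelihood(cells, fit.structure, w)
    nll_min = -fit.loglik
    se = _wald_se(fit)
    names = fit.structure.param_names()
    struct = fit.structure
    plain_gompertz = (
        struct.family == "gompertz" and not struct.alpha_terms and not struct.beta_terms
    )
    if plain_gompertz:
        times = np.concatenate(list(cells.values()))
    ci: dict[str, tuple[float, float]] = {}
    used_method = method
    for j, name in enumerate(names):
        if method == "profile":
            if plain_gompertz:
                make = lambda: _gompertz_profile_dev(times, fit.working, nll_min, j)
            else:
                make = lambda: _make_profile_dev(objective, fit.working, nll_min, j)
            lo = _profile_bound(make(), fit.working, j, se[j], side=-1)
            hi = _profile_bound(make(), fit.working, j, se[j], side=+1)
            if lo is None or hi is None:
                log.warning("profile CI for %s failed to bracket; using Wald", name)
                lo = fit.working[j] - 1.959964 * se[j]
                hi = fit.working[j] + 1.959964 * se[j]
                used_method = "profile+wald-fallback"
        else:
            lo = fit.working[j] - 1.959964 * se[j]
            hi = fit.working[j] + 1.959964 * se[j]
        ci[name] = (math.exp(lo), math.exp(hi))
    return replace(fit, ci95=ci, ci_method=used_method)
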