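"""Random-intercept Gaussian mixed model for nightly calling effort.

The response is seconds of advertisement calling per night (15-h recording
window, so values live in [0, 54000]).  Fixed effects are polynomial terms
in age and lifespan, the diet and mating contrasts, and their products;
cricket identity enters as a random intercept to absorb between-male
differences and within-male temporal correlation.

The model is fitted by full maximum likelihood (not REML, so AIC
comparisons across fixed-effect structures are valid), implemented here
directly via variance-ratio profiling: for each theta = sigma_u^2 /
sigma_e^2 the fixed effects and residual variance have closed-form
generalised-least-squares solutions, leaving a one-dimensional
optimisation over theta.  With the Woodbury identity the per-group
inverse is (I - theta/(1 + theta*n_i) * J), so only group-wise sums of
the design matrix and response are needed and each profile evaluation is
O(number of groups), independent of the number of rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .battery import akaike_weights
from .errors import ConfigurationError, DataError, UsageError

__all__ = [
    "CALLING_MAX_S",
    "TABLE_TERMS",
    "CallingModelSpec",
    "MixedFitResult",
    "build_design",
    "fit_lmm",
    "fit_calling_model",
    "compare_calling_models",
    "mean_calling_ttest",
]

log = logging.getLogger(__name__)

#: seconds in the 15-h nightly recording window (18:00-09:00)
CALLING_MAX_S = 54000.0

#: fixed-effect structure of the best-fit calling model
TABLE_TERMS = (
    "intercept",
    "diet",
    "mating",
    "age",
    "lifespan",
    "age2",
    "lifespan2",
    "diet:age",
    "diet:age2",
    "age:lifespan",
)

_BASE_COLUMNS = ("intercept", "diet", "mating", "age", "lifespan", "age2", "lifespan2")


@dataclass(frozen=True)
class CallingModelSpec:
    """Fixed-effect coefficients plus the two variance components.

    Coefficient units are seconds (contrasts, intercept) or seconds per
    day^k (covariate terms); ``sigma_u`` is the between-male random-
    intercept SD and ``sigma_e`` the residual SD, both in seconds.
    Baseline coding: diet C, mated.
    """

    fixed_terms: tuple[str, ...]
    coefficients: dict[str, float]
    sigma_u: float
    sigma_e: float

    def __post_init__(self) -> None:
        if set(self.fixed_terms) != set(self.coefficients):
            raise ConfigurationError("coefficients must match fixed_terms exactly")
        if self.sigma_u < 0:
            raise ConfigurationError("sigma_u must be >= 0")
        if self.sigma_e <= 0:
            raise ConfigurationError("sigma_e must be > 0")


def _column(term: str, frame: pd.DataFrame) -> np.ndarray:
    """One design column; product terms multiply their base columns."""
    base = {
        "intercept": lambda: np.ones(len(frame)),
        "diet": lambda: (frame["diet"].to_numpy() == "P").astype(float),
        "mating": lambda: (frame["mating"].to_numpy() == "virgin").astype(float),
        "age": lambda: frame["age"].to_numpy(dtype=float),
        "lifespan": lambda: frame["lifespan"].to_numpy(dtype=float),
        "age2": lambda: frame["age"].to_numpy(dtype=float) ** 2,
        "lifespan2": lambda: frame["lifespan"].to_numpy(dtype=float) ** 2,
    }
    if term in base:
        return base[term]()
    parts = term.split(":")
    if all(p in _BASE_COLUMNS and p != "intercept" for p in parts) and 2 <= len(parts) <= 3:
        col = np.ones(len(frame))
        for p in parts:
            col = col * base[p]()
        return col
    raise ConfigurationError(
        f"unknown model term {term!r}; build terms from {_BASE_COLUMNS} "
        "and ':' products of them"
    )


def build_design(
    frame: pd.DataFrame, terms: Sequence[str] = TABLE_TERMS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design matrix, response and grouping vector for the calling model.

    ``frame`` needs columns id, diet, mating, age, lifespan, calling_s
    (one row per nightly observation; lifespan repeated within male).
    Columns come out in the order of ``terms``; baseline coding is diet C
    and mated, so e.g. the diet:age column is zero for every diet-C male.
    """
    required = {"id", "diet", "mating", "age", "lifespan", "calling_s"}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"calling table is missing columns {sorted(missing)}")
    X = np.column_stack([_column(t, frame) for t in terms])
    y = frame["calling_s"].to_numpy(dtype=float)
    groups = frame["id"].to_numpy()
    return X, y, groups


@dataclass
class MixedFitResult:
    """ML fit of the random-intercept model."""

    terms: tuple[str, ...]
    coefficients: dict[str, float]
    se: dict[str, float]
    sigma_u: float
    sigma_e: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    at_boundary: bool  # theta optimum at 0: plain regression

    @property
    def n_params(self) -> int:
        return len(self.terms) + 2  # fixed effects + two variance components

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def spec(self) -> CallingModelSpec:
        return CallingModelSpec(self.terms, dict(self.coefficients), self.sigma_u, self.sigma_e)

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "coefficients": self.coefficients,
            "se": self.se,
            "sigma_u": self.sigma_u,
            "sigma_e": self.sigma_e,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "at_boundary": self.at_boundary,
        }


class _Sufficient:
    """Per-group sufficient statistics for the profiled likelihood."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        Xs, ys, gs = X[order], y[order], groups[order]
        _, starts, counts = np.unique(gs, return_index=True, return_counts=True)
        self.n, self.p = X.shape
        self.G = counts.size
        self.counts = counts.astype(float)
        self.XtX = Xs.T @ Xs
        self.Xty = Xs.T @ ys
        self.yty = float(ys @ ys)
        self.Sx = np.add.reduceat(Xs, starts, axis=0)       # group sums of X
        self.Sy = np.add.reduceat(ys, starts)               # group sums of y

    def gls(self, theta: float):
        """GLS solution and profile log-likelihood at variance ratio theta."""
        w = theta / (1.0 + theta * self.counts)
        A = self.XtX - (self.Sx * w[:, None]).T @ self.Sx
        b = self.Xty - self.Sx.T @ (w * self.Sy)
        q = self.yty - float(w @ (self.Sy**2))
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            raise DataError(_collinear_message(A))
        rss = q - float(beta @ b)
        if rss <= 0:
            return beta, A, np.nan, -np.inf
        sigma_e2 = rss / self.n
        loglik = (
            -0.5 * self.n * (math.log(2.0 * math.pi * sigma_e2) + 1.0)
            - 0.5 * float(np.sum(np.log1p(theta * self.counts)))
        )
        return beta, A, sigma_e2, loglik


def _collinear_message(A: np.ndarray) -> str:
    # name the columns implicated in the rank deficiency
    _, s, vt = np.linalg.svd(A)
    bad = np.where(s < s.max() * 1e-10)[0]
    cols = sorted({int(j) for i in bad for j in np.argsort(-np.abs(vt[i]))[:2]})
    return f"design matrix is rank deficient; columns {cols} appear collinear"


def fit_lmm(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    term_names: Sequence[str] | None = None,
    *,
    reml: bool = False,
) -> MixedFitResult:
    """Fit the random-intercept model by maximum likelihood.

    Profiles the likelihood over theta = sigma_u^2 / sigma_e^2 (fixed
    effects and sigma_e^2 solved in closed form at each theta) and
    optimises theta on a log grid refined by bounded search.  A theta
    optimum at zero is valid — the model collapses to ordinary
    regression — and is flagged ``at_boundary``.

    ``reml=True`` applies the restricted-likelihood correction; its
    likelihood is not comparable across fixed-effect structures, so AIC
    from a REML fit should not be used for model selection.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    groups = np.asarray(groups)
    if X.ndim != 2 or X.shape[0] != y.size or groups.size != y.size:
        raise UsageError("X, y and groups must have matching row counts")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError(_collinear_message(X.T @ X))
    suff = _Sufficient(X, y, groups)
    if suff.G < 2:
        raise DataError("at least 2 groups are required for a random intercept")

    def negloglik_logtheta(u: float) -> float:
        _, _, _, ll = suff.gls(math.exp(u))
        ll = _reml_adjust(ll, suff, math.exp(u)) if reml else ll
        return -ll

    # coarse log-spaced scan, then bounded refinement around the best point
    grid = np.linspace(-12.0, 8.0, 41)
    vals = np.array([negloglik_logtheta(u) for u in grid])
    u0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        negloglik_logtheta, bounds=(u0 - 1.5, u0 + 1.5), method="bounded",
        options={"xatol": 1e-10},
    )
    theta = math.exp(res.x)
    ll_theta = -res.fun
    # compare against the theta = 0 boundary (ordinary regression)
    _, _, _, ll0 = suff.gls(0.0)
    ll0 = _reml_adjust(ll0, suff, 0.0) if reml else ll0
    at_boundary = ll0 >= ll_theta
    if at_boundary:
        theta, ll_theta = 0.0, ll0
        log.warning("variance-ratio optimum at 0: random intercept collapses to OLS")
    beta, A, sigma_e2, loglik = suff.gls(theta)
    if reml:
        loglik = _reml_adjust(loglik, suff, theta)
    cov = sigma_e2 * np.linalg.inv(A)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    names = tuple(term_names) if term_names is not None else tuple(
        f"x{i}" for i in range(X.shape[1])
    )
    return MixedFitResult(
        terms=names,
        coefficients={n: float(b) for n, b in zip(names, beta)},
        se={n: float(s) for n, s in zip(names, se)},
        sigma_u=math.sqrt(theta * sigma_e2),
        sigma_e=math.sqrt(sigma_e2),
        loglik=float(loglik),
        n_obs=suff.n,
        n_groups=suff.G,
        converged=bool(np.isfinite(loglik)),
        at_boundary=bool(at_boundary),
    )


def _reml_adjust(ll: float, suff: _Sufficient, theta: float) -> float:
    """Restricted-likelihood correction -0.5 log|X' V^-1 X| (+ constant)."""
    if not np.isfinite(ll):
        return ll
    w = theta / (1.0 + theta * suff.counts)
    A = suff.XtX - (suff.Sx * w[:, None]).T @ suff.Sx
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    # ML sigma_e2 vs REML's n-p divisor is absorbed into the profile; the
    # simple adjustment below is adequate for the flagged, non-default path.
    return ll - 0.5 * logdet + 0.5 * suff.p * math.log(2.0 * math.pi)


def fit_calling_model(
    frame: pd.DataFrame, terms: Sequence[str] = TABLE_TERMS, **kwargs
) -> MixedFitResult:
    """Convenience wrapper: build the design from a calling table and fit."""
    X, y, groups = build_design(frame, terms)
    return fit_lmm(X, y, groups, term_names=terms, **kwargs)


def compare_calling_models(
    candidates: Sequence[Sequence[str]], frame: pd.DataFrame
) -> pd.DataFrame:
    """AIC table over candidate fixed-effect term lists (same rows for all).

    Failed candidates are kept in the table, flagged, and excluded from the
    Akaike-weight normalisation.
    """
    rows = []
    for terms in candidates:
        label = " + ".join(terms)
        try:
            fit = fit_calling_model(frame, tuple(terms))
            rows.append({"model": label, "k": fit.n_params, "loglik": fit.loglik,
                         "AIC": fit.aic, "converged": fit.converged})
        except (DataError, ConfigurationError) as exc:
            log.warning("candidate %r failed: %s", label, exc)
            rows.append({"model": label, "k": len(terms) + 2, "loglik": np.nan,
                         "AIC": np.nan, "converged": False})
    frame_out = pd.DataFrame(rows)
    ok = frame_out["converged"] & np.isfinite(frame_out["AIC"])
    frame_out["dAIC"] = np.nan
    frame_out["weight"] = np.nan
    if ok.any():
        aics = frame_out.loc[ok, "AIC"].to_numpy()
        frame_out.loc[ok, "dAIC"] = aics - aics.min()
        frame_out.loc[ok, "weight"] = akaike_weights(aics)
    return frame_out.sort_values("AIC", na_position="last").reset_index(drop=True)


def mean_calling_ttest(frame: pd.DataFrame, mating: str) -> dict:
    """Welch t-test of per-male mean calling effort, diet C vs diet P,
    within one mating group.  A descriptive convenience, not part of the
    mixed-model inference."""
    sub = frame[frame["mating"] == mating]
    means = sub.groupby(["id", "diet"])["calling_s"].mean().reset_index()
    c = means.loc[means["diet"] == "C", "calling_s"]
    p = means.loc[means["diet"] == "P", "calling_s"]
    if len(c) < 2 or len(p) < 2:
        raise DataError("need at least two males per diet for the t-test")
    res = stats.ttest_ind(c, p, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue),
            "n_C": int(len(c)), "n_P": int(len(p))}
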