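"""Parametric mortality models for adult insect cohorts.

Six hazard families are supported, the standard tool-kit of demographic
senescence analysis:

========  =======================================================  ==========
family    hazard mu(x)                                             parameters
========  =======================================================  ==========
constant            alpha                                          alpha
gompertz            alpha * exp(beta*x)                            alpha, beta
gompertz_makeham    c + alpha * exp(beta*x)                        alpha, beta, c
logistic            alpha*exp(beta*x) /
                      (1 + (s*alpha/beta)*(exp(beta*x) - 1))       alpha, beta, s
logistic_makeham    c + logistic hazard                            alpha, beta, s, c
weibull             a * b * x**(b-1)                               a, b
========  =======================================================  ==========

``alpha`` is the baseline mortality rate (the hazard at adult age 0,
day^-1), ``beta`` the exponential rate of ageing (day^-1), ``c`` an additive
age-independent (Makeham) component, ``s`` a dimensionless late-life
deceleration shape, and ``a``/``b`` the Weibull scale and shape.  Ages are
continuous non-negative reals in days of adult life, day 0 = eclosion.

All functions are vectorised over age; scalars in give scalars out.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DomainError

__all__ = [
    "FAMILIES",
    "HazardSpec",
    "hazard",
    "survival",
    "log_survival",
    "log_density",
    "density",
    "quantile",
    "simulate_death_times",
]

#: parameter names, in canonical order, per family
FAMILIES: dict[str, tuple[str, ...]] = {
    "constant": ("alpha",),
    "gompertz": ("alpha", "beta"),
    "gompertz_makeham": ("alpha", "beta", "c"),
    "logistic": ("alpha", "beta", "s"),
    "logistic_makeham": ("alpha", "beta", "s", "c"),
    "weibull": ("a", "b"),
}

#: parameters allowed to touch zero (the rest must be strictly positive)
_ZERO_OK = frozenset({"c", "s"})

# below this, beta (or s) is routed to its analytic limit to avoid
# catastrophic cancellation in (e^{beta x} - 1)/beta style expressions
_TINY = 1e-10


@dataclass(frozen=True)
class HazardSpec:
    """A hazard family plus its parameter vector.

    Parameters are validated at construction: all must be finite, strictly
    positive except ``c`` and ``s`` which may be zero.
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise DomainError(
                f"unknown hazard family {self.family!r}; "
                f"choose from {sorted(FAMILIES)}"
            )
        names = FAMILIES[self.family]
        got = dict(self.params)
        missing = [n for n in names if n not in got]
        extra = [n for n in got if n not in names]
        if missing or extra:
            raise DomainError(
                f"family {self.family!r} takes parameters {list(names)}; "
                f"missing {missing}, unexpected {extra}"
            )
        clean = {}
        for name in names:
            value = float(got[name])
            if not math.isfinite(value):
                raise DomainError(f"parameter {name!r} must be finite, got {value}")
            if name in _ZERO_OK:
                if value < 0:
                    raise DomainError(f"parameter {name!r} must be >= 0, got {value}")
            elif value <= 0:
                raise DomainError(f"parameter {name!r} must be > 0, got {value}")
            clean[name] = value
        object.__setattr__(self, "params", clean)

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def to_json(self) -> str:
        return json.dumps({"family": self.family, "params": dict(self.params)})

    @classmethod
    def from_json(cls, text: str) -> "HazardSpec":
        payload = json.loads(text)
        return cls(payload["family"], payload["params"])


def _as_age(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(~np.isfinite(arr)):
        raise DomainError("age must be finite and >= 0")
    return arr


def _maybe_scalar(value: np.ndarray, x) -> float | np.ndarray:
    if np.isscalar(x) or (isinstance(x, np.ndarray) and x.ndim == 0):
        return float(value)
    return value


def hazard(spec: HazardSpec, x) -> float | np.ndarray:
    """Instantaneous mortality rate mu(x) at adult age ``x`` (day^-1)."""
    t = _as_age(x)
    p = spec.params
    fam = spec.family
    if fam == "constant":
        out = np.full_like(t, p["alpha"])
    elif fam == "gompertz":
        out = p["alpha"] * np.exp(p["beta"] * t)
    elif fam == "gompertz_makeham":
        out = p["c"] + p["alpha"] * np.exp(p["beta"] * t)
    elif fam in ("logistic", "logistic_makeham"):
        out = _logistic_hazard(p, t)
        if fam == "logistic_makeham":
            out = out + p["c"]
    elif fam == "weibull":
        a, b = p["a"], p["b"]
        with np.errstate(divide="ignore"):
            out = a * b * np.power(t, b - 1.0)
    return _maybe_scalar(out, x)


def _logistic_hazard(p: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    alpha, beta, s = p["alpha"], p["beta"], p["s"]
    if s < _TINY or beta < _TINY:
        # s -> 0 recovers Gompertz; beta -> 0 recovers constant hazard
        return alpha * np.exp(beta * t)
    return alpha * np.exp(beta * t) / (1.0 + (s * alpha / beta) * np.expm1(beta * t))


def log_survival(spec: HazardSpec, x) -> float | np.ndarray:
    """log S(x), the log probability of surviving past age ``x``."""
    t = _as_age(x)
    p = spec.params
    fam = spec.family
    if fam == "constant":
        out = -p["alpha"] * t
    elif fam in ("gompertz", "gompertz_makeham"):
        alpha, beta = p["alpha"], p["beta"]
        if beta < _TINY:
            out = -alpha * t
        else:
            out = -(alpha / beta) * np.expm1(beta * t)
        if fam == "gompertz_makeham":
            out = out - p["c"] * t
    elif fam in ("logistic", "logistic_makeham"):
        alpha, beta, s = p["alpha"], p["beta"], p["s"]
        if beta < _TINY:
            out = -alpha * t
        elif s < _TINY:
            out = -(alpha / beta) * np.expm1(beta * t)
        else:
            out = -np.log1p((s * alpha / beta) * np.expm1(beta * t)) / s
        if fam == "logistic_makeham":
            out = out - p["c"] * t
    elif fam == "weibull":
        out = -p["a"] * np.power(t, p["b"])
    return _maybe_scalar(out, x)


def survival(spec: HazardSpec, x) -> float | np.ndarray:
    """Survivorship S(x) = exp(-integral of the hazard over [0, x])."""
    ls = log_survival(spec, x)
    return math.exp(ls) if np.isscalar(ls) else np.exp(ls)


def log_density(spec: HazardSpec, x) -> float | np.ndarray:
    """Log of the death-age density, log mu(x) + log S(x)."""
    t = _as_age(x)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        mu = np.asarray(hazard(spec, t), dtype=float)
        ls = np.asarray(log_survival(spec, t), dtype=float)
        out = np.log(mu) + ls
        # far in the tail the hazard overflows while log S -> -inf; the
        # density there is zero
        out = np.where(np.isneginf(ls) | ~np.isfinite(mu), -np.inf, out)
    return _maybe_scalar(np.asarray(out), x)


def density(spec: HazardSpec, x) -> float | np.ndarray:
    return np.exp(log_density(spec, x))


def _check_p(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise DomainError("probability p must lie strictly in (0, 1)")
    return arr


def quantile(spec: HazardSpec, p) -> float | np.ndarray:
    """Age by which a fraction ``p`` of the cohort has died.

    Closed form where one exists (constant, Gompertz, logistic, Weibull);
    vectorised bisection on the survival function for the Makeham variants.
    Satisfies survival(quantile(p)) = 1 - p to ~1e-12.
    """
    prob = _check_p(p)
    pars = spec.params
    fam = spec.family
    # -log(1-p), the target cumulative hazard
    target = -np.log1p(-prob)
    if fam == "constant":
        out = target / pars["alpha"]
    elif fam == "gompertz":
        alpha, beta = pars["alpha"], pars["beta"]
        if beta < _TINY:
            out = target / alpha
        else:
            out = np.log1p((beta / alpha) * target) / beta
    elif fam == "logistic":
        alpha, beta, s = pars["alpha"], pars["beta"], pars["s"]
        if beta < _TINY:
            out = target / alpha
        elif s < _TINY:
            out = np.log1p((beta / alpha) * target) / beta
        else:
            # S = (1 + (s a/b) expm1(b x))^{-1/s} = 1-p
            out = np.log1p((beta / (s * alpha)) * np.expm1(s * target)) / beta
    elif fam == "weibull":
        out = np.power(target / pars["a"], 1.0 / pars["b"])
    else:  # Makeham variants: monotone bisection on cumulative hazard
        out = _quantile_bisect(spec, np.atleast_1d(target))
        out = out.reshape(np.shape(prob))
    return _maybe_scalar(np.asarray(out), p)


def _quantile_bisect(spec: HazardSpec, target: np.ndarray) -> np.ndarray:
    """Solve -log S(x) = target elementwise by bracketing + bisection."""
    hi = np.ones_like(target)
    for _ in range(200):
        todo = -log_survival(spec, hi) < target
        if not np.any(todo):
            break
        hi[todo] *= 2.0
    lo = np.zeros_like(target)
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        below = -log_survival(spec, mid) < target
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def simulate_death_times(spec: HazardSpec, n: int, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. death ages by inverse-CDF sampling.

    ``seed`` may be an int or a ``numpy.random.Generator``; the same seed
    always reproduces the same sample.
    """
    if n < 1:
        raise DomainError(f"sample size must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(int(n))
    # keep u away from the closed endpoints
    u = np.clip(u, 1e-16, 1.0 - 1e-16)
    return np.asarray(quantile(spec, u), dtype=float).reshape(-1)
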