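"""Model batteries: enumerate treatment structures, rank them by AIC,
compute Akaike weights, and run likelihood-ratio tests between nested fits.

The battery's unit is a :class:`~cricketsen.fitting.ModelStructure`; the
default enumeration crosses every hierarchical term set on the baseline
parameter with every term set on the ageing-rate parameter (5 x 5 = 25
Gompertz structures) and appends the constant-hazard "no senescence"
model.  Sexes are analysed in separate batteries; a pooled-versus-
sex-stratified likelihood-ratio test is provided as a dedicated step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError
from .fitting import FitResult, IndividualRecord, ModelStructure, fit_mortality

__all__ = [
    "BatteryResult",
    "enumerate_structures",
    "run_battery",
    "akaike_weights",
    "likelihood_ratio_test",
    "sex_lrt",
]

log = logging.getLogger(__name__)


def _hierarchical_term_sets(factors: Sequence[str]) -> list[tuple[str, ...]]:
    """All term sets obeying marginality: the interaction only ever appears
    together with both main effects."""
    factors = tuple(factors)
    sets: list[tuple[str, ...]] = [()]
    for f in factors:
        sets.append((f,))
    if len(factors) == 2:
        sets.append(factors)
        sets.append(factors + ("diet:mated",))
    return sets


def enumerate_structures(
    factors: Sequence[str] = ("diet", "mated"),
    family: str = "gompertz",
    include_constant: bool = True,
) -> list[ModelStructure]:
    """Every treatment structure for the battery.

    With both factors this yields 25 Gompertz structures (5 hierarchical
    term sets on alpha x 5 on beta) plus, when ``include_constant``, the
    no-senescence constant-hazard model — 26 in total.
    """
    term_sets = _hierarchical_term_sets(factors)
    structures = [
        ModelStructure(family=family, alpha_terms=a, beta_terms=b)
        for a in term_sets
        for b in term_sets
    ]
    if include_constant:
        structures.append(ModelStructure(family="constant"))
    return structures


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    """Akaike weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - np.min(aics)
    raw = np.exp(-0.5 * delta)
    return raw / np.sum(raw)


@dataclass
class BatteryResult:
    """Fits of a candidate set, ordered by AIC (best first)."""

    fits: list[FitResult]
    delta_aic: np.ndarray
    akaike_weight: np.ndarray

    @property
    def best(self) -> FitResult:
        return self.fits[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [f.structure.label for f in self.fits],
                "k": [f.n_params for f in self.fits],
                "loglik": [f.loglik for f in self.fits],
                "AIC": [f.aic for f in self.fits],
                "dAIC": self.delta_aic,
                "weight": self.akaike_weight,
                "converged": [f.converged for f in self.fits],
            }
        )

    def to_dict(self) -> dict:
        frame = self.to_frame()
        return {"models": frame.to_dict(orient="records"), "best": self.best.to_dict()}


def run_battery(
    records: Sequence[IndividualRecord],
    structures: Sequence[ModelStructure] | None = None,
    *,
    use_aicc: bool = False,
    **fit_kwargs,
) -> BatteryResult:
    """Fit every candidate structure to the same records and rank by AIC.

    Non-converged fits are retained (flagged, sorted last) but excluded
    from the weight normalisation.  Ties in AIC are broken in favour of
    fewer parameters.  ``use_aicc`` switches to the small-sample corrected
    criterion; the plain AIC is the default.
    """
    if structures is None:
        structures = enumerate_structures()
    fit_kwargs.setdefault("n_restarts", 2)
    # warm-start every structure from its family's no-effects optimum
    base_fits: dict[str, FitResult] = {}
    order = np.argsort([s.n_params for s in structures], kind="stable")
    fits_by_pos: dict[int, FitResult] = {}
    for pos in order:
        s = structures[pos]
        extra = []
        base = base_fits.get(s.family)
        if base is not None and base.working is not None:
            extra.append(s.embed_working(base.structure, base.working))
        fit = fit_mortality(records, s, extra_starts=extra, **fit_kwargs)
        if s.family not in base_fits and not s.alpha_terms and not s.beta_terms:
            base_fits[s.family] = fit
        fits_by_pos[pos] = fit
    fits = [fits_by_pos[i] for i in range(len(structures))]

    n = len(records)

    def criterion(f: FitResult) -> float:
        aic = f.aic
        if use_aicc and n - f.n_params - 1 > 0:
            aic += 2.0 * f.n_params * (f.n_params + 1) / (n - f.n_params - 1)
        return aic

    ok = [f for f in fits if f.converged]
    bad = [f for f in fits if not f.converged]
    if bad:
        log.warning("%d of %d fits did not converge; excluded from weights", len(bad), len(fits))
    if not ok:
        raise UsageError("no structure in the battery converged")
    ok.sort(key=lambda f: (criterion(f), f.n_params))
    aics = np.array([criterion(f) for f in ok])
    weights = akaike_weights(aics)
    fits_sorted = ok + bad
    delta = np.concatenate([aics - aics[0], np.full(len(bad), np.nan)])
    weights_full = np.concatenate([weights, np.full(len(bad), np.nan)])
    return BatteryResult(fits=fits_sorted, delta_aic=delta, akaike_weight=weights_full)


def _is_nested(reduced: ModelStructure, full: ModelStructure) -> bool:
    if reduced.family != full.family:
        # constant hazard is the beta -> 0 boundary of Gompertz; treat as
        # non-nested for the chi-square LRT (boundary problem).
        return False
    return set(reduced.alpha_terms) <= set(full.alpha_terms) and set(
        reduced.beta_terms
    ) <= set(full.beta_terms)


def likelihood_ratio_test(
    full: FitResult, reduced: FitResult, *, tol: float = 1e-6
) -> tuple[float, int, float]:
    """Chi-square likelihood-ratio test of a reduced model inside a full one.

    Returns ``(statistic, df, p)`` with statistic = 2(l_full - l_reduced)
    and df = the difference in parameter counts.
    """
    if full.n_params < reduced.n_params or not _is_nested(reduced.structure, full.structure):
        raise UsageError(
            f"model {reduced.structure.label!r} is not nested in {full.structure.label!r}"
        )
    return _lrt_from_logliks(full.loglik, reduced.loglik,
                             full.n_params - reduced.n_params, tol=tol)


def _lrt_from_logliks(ll_full: float, ll_reduced: float, df: int,
                      tol: float = 1e-6) -> tuple[float, int, float]:
    statistic = 2.0 * (ll_full - ll_reduced)
    if statistic < -tol:
        raise UsageError(
            f"full-model log-likelihood is below the reduced model's by "
            f"{-statistic / 2:.3g}; the optimiser likely failed"
        )
    statistic = max(statistic, 0.0)
    if df == 0 or statistic == 0.0:  # identical models
        return statistic, df, 1.0
    return statistic, df, float(stats.chi2.sf(statistic, df))


def sex_lrt(
    records: Sequence[IndividualRecord],
    structure: ModelStructure | None = None,
    **fit_kwargs,
) -> dict:
    """Test whether mortality differs between the sexes.

    Fits the full treatment structure (diet, mating and their interaction on
    both Gompertz parameters) separately to males and females — equivalent
    to a model with sex crossed with every term — and compares, by a
    chi-square likelihood-ratio test, against the same structure fitted to
    the pooled data.  With the default 8-parameter structure the test has
    8 degrees of freedom.
    """
    if structure is None:
        structure = ModelStructure(
            family="gompertz",
            alpha_terms=("diet", "mated", "diet:mated"),
            beta_terms=("diet", "mated", "diet:mated"),
        )
    males = [r for r in records if r.sex == "male"]
    females = [r for r in records if r.sex == "female"]
    if not males or not females:
        raise UsageError("sex_lrt requires records from both sexes")
    fit_m = fit_mortality(males, structure, **fit_kwargs)
    fit_f = fit_mortality(females, structure, **fit_kwargs)
    fit_pooled = fit_mortality(list(records), structure, **fit_kwargs)
    ll_full = fit_m.loglik + fit_f.loglik
    df = structure.n_params  # one extra copy of every parameter
    statistic, df, p = _lrt_from_logliks(ll_full, fit_pooled.loglik, df)
    return {
        "statistic": statistic,
        "df": df,
        "p": p,
        "loglik_sexed": ll_full,
        "loglik_pooled": fit_pooled.loglik,
        "fit_male": fit_m,
        "fit_female": fit_f,
        "fit_pooled": fit_pooled,
    }
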