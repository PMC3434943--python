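"""Maximum-likelihood mortality fitting: likelihoods, MLEs, CIs."""

import math

import numpy as np
import pytest
from scipy import stats

from cricketsen import (
    ConfigurationError,
    DataError,
    HazardSpec,
    IndividualRecord,
    ModelStructure,
    confint,
    fit_mortality,
    neg_log_likelihood,
    simulate_death_times,
)
from conftest import make_records


def test_single_record_gompertz_loglikelihood():
    # one death at t: -[ln(alpha) + beta*t + (alpha/beta)(1 - e^{beta t})]
    alpha, beta, t = 0.01, 0.04, 30.0
    rec = [IndividualRecord("a", "male", "C", "mated", t)]
    w = np.log([alpha, beta])
    expected = -(math.log(alpha) + beta * t + (alpha / beta) * (1 - math.exp(beta * t)))
    assert neg_log_likelihood(rec, ModelStructure("gompertz"), w) == pytest.approx(
        expected, rel=1e-12
    )


def test_constant_family_exponential_identity():
    # NLL = -(n ln(alpha) - alpha * T); MLE alpha = n / T
    times = np.array([3.0, 11.0, 7.5, 20.0, 2.2, 9.0])
    recs = make_records(times)
    n, total = len(times), float(times.sum())
    alpha = 0.07
    got = neg_log_likelihood(recs, ModelStructure("constant"), np.log([alpha]))
    assert got == pytest.approx(-(n * math.log(alpha) - alpha * total), rel=1e-12)
    fit = fit_mortality(recs, ModelStructure("constant"))
    assert fit.estimates["alpha"] == pytest.approx(n / total, rel=1e-6)


def test_full_structure_decomposes_into_cell_fits():
    # with every effect on both parameters, the likelihood factorises and
    # the joint fit equals four independent single-cell fits
    rng_specs = {
        ("C", "mated"): HazardSpec("gompertz", {"alpha": 0.008, "beta": 0.05}),
        ("C", "virgin"): HazardSpec("gompertz", {"alpha": 0.012, "beta": 0.03}),
        ("P", "mated"): HazardSpec("gompertz", {"alpha": 0.004, "beta": 0.045}),
        ("P", "virgin"): HazardSpec("gompertz", {"alpha": 0.006, "beta": 0.025}),
    }
    records, ll_cells = [], 0.0
    for i, ((diet, mating), spec) in enumerate(sorted(rng_specs.items())):
        times = simulate_death_times(spec, 300, seed=100 + i)
        cell = make_records(times, diet=diet, mating=mating, prefix=f"{diet}{mating}")
        records += cell
        ll_cells += fit_mortality(cell, ModelStructure("gompertz")).loglik
    full = ModelStructure(
        "gompertz",
        alpha_terms=("diet", "mated", "diet:mated"),
        beta_terms=("diet", "mated", "diet:mated"),
    )
    joint = fit_mortality(records, full)
    assert joint.loglik == pytest.approx(ll_cells, abs=1e-3)
    assert joint.n_params == 8


def test_parameter_recovery_moderate_n():
    spec = HazardSpec("gompertz", {"alpha": 0.0101, "beta": 0.0264})
    recs = make_records(simulate_death_times(spec, 20_000, seed=5))
    fit = fit_mortality(recs, ModelStructure("gompertz"))
    assert fit.converged
    assert fit.estimates["alpha"] == pytest.approx(0.0101, rel=0.05)
    assert fit.estimates["beta"] == pytest.approx(0.0264, rel=0.05)
    # the optimum cannot be worse than the generating parameters
    nll_truth = neg_log_likelihood(recs, ModelStructure("gompertz"),
                                   np.log([0.0101, 0.0264]))
    assert fit.loglik >= -nll_truth - 1e-6


def test_record_order_does_not_change_output():
    spec = HazardSpec("gompertz", {"alpha": 0.008, "beta": 0.04})
    recs = make_records(simulate_death_times(spec, 500, seed=8), diet="C") + make_records(
        simulate_death_times(spec, 500, seed=9), diet="P", prefix="p"
    )
    st = ModelStructure("gompertz", alpha_terms=("diet",))
    a = fit_mortality(recs, st)
    b = fit_mortality(list(reversed(recs)), st)
    assert a.estimates == b.estimates
    assert a.loglik == b.loglik


def test_exponential_profile_ci_matches_exact_gamma_ci():
    rng = np.random.default_rng(12)
    times = rng.exponential(scale=25.0, size=100)
    recs = make_records(times)
    fit = fit_mortality(recs, ModelStructure("constant"), ci="profile")
    n, total = len(times), float(times.sum())
    # exact equal-tailed CI for an exponential rate via the chi-square
    exact = (stats.chi2.ppf(0.025, 2 * n) / (2 * total),
             stats.chi2.ppf(0.975, 2 * n) / (2 * total))
    lo, hi = fit.ci95["alpha"]
    assert lo == pytest.approx(exact[0], rel=0.01)
    assert hi == pytest.approx(exact[1], rel=0.01)
    assert lo < fit.estimates["alpha"] < hi


def test_profile_and_wald_agree_at_large_n():
    spec = HazardSpec("gompertz", {"alpha": 0.0078, "beta": 0.0417})
    recs = make_records(simulate_death_times(spec, 100_000, seed=21))
    fit = fit_mortality(recs, ModelStructure("gompertz"), n_restarts=1)
    prof = confint(fit, "profile")
    wald = confint(fit, "wald")
    for name in ("alpha", "beta"):
        for a, b in zip(prof.ci95[name], wald.ci95[name]):
            assert a == pytest.approx(b, rel=0.05)


def test_ci_reported_only_for_estimated_parameters():
    spec = HazardSpec("gompertz", {"alpha": 0.008, "beta": 0.04})
    recs = make_records(simulate_death_times(spec, 800, seed=2))
    fit = fit_mortality(recs, ModelStructure("gompertz"), ci="wald")
    assert set(fit.ci95) == {"alpha", "beta"}
    for name, (lo, hi) in fit.ci95.items():
        assert lo < fit.estimates[name] < hi


def test_structure_validation():
    with pytest.raises(ConfigurationError, match="marginality"):
        ModelStructure("gompertz", alpha_terms=("diet:mated",))
    with pytest.raises(ConfigurationError):
        ModelStructure("constant", beta_terms=("diet",))
    with pytest.raises(ConfigurationError, match="unknown"):
        ModelStructure("gompertz", alpha_terms=("sex",))


def test_parameter_vector_length_checked():
    recs = make_records([5.0, 8.0, 13.0])
    with pytest.raises(ConfigurationError, match="parameters"):
        neg_log_likelihood(recs, ModelStructure("gompertz"), np.array([0.1]))


def test_small_cell_is_a_data_error():
    recs = make_records([5.0, 8.0], diet="C") + make_records([9.0], diet="P", prefix="p")
    with pytest.raises(DataError, match="diet=P"):
        fit_mortality(recs, ModelStructure("gompertz", alpha_terms=("diet",)))


def test_record_validation():
    with pytest.raises(DataError, match="sex"):
        IndividualRecord("x", "other", "C", "mated", 10.0)
    with pytest.raises(DataError, match="lifespan"):
        IndividualRecord("x", "male", "C", "mated", -1.0)
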