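"""Random-intercept calling-effort model: design, ML fit, model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from cricketsen import (
    ConfigurationError,
    DataError,
    ExperimentConfig,
    TABLE_TERMS,
    build_design,
    compare_calling_models,
    fit_calling_model,
    fit_lmm,
    generate_experiment,
    join_calling,
    mean_calling_ttest,
)
from cricketsen.simulate import DEFAULT_HAZARDS


def _frame(rows):
    return pd.DataFrame(rows)


def _toy_frame():
    return _frame(
        [
            {"id": "a", "diet": "C", "mating": "mated", "age": 4.0, "lifespan": 20.0, "calling_s": 100.0},
            {"id": "a", "diet": "C", "mating": "mated", "age": 9.0, "lifespan": 20.0, "calling_s": 140.0},
            {"id": "b", "diet": "P", "mating": "virgin", "age": 4.0, "lifespan": 30.0, "calling_s": 90.0},
            {"id": "b", "diet": "P", "mating": "virgin", "age": 14.0, "lifespan": 30.0, "calling_s": 160.0},
        ]
    )


def test_design_columns():
    frame = _toy_frame()
    X, y, groups = build_design(frame, ("intercept", "age2", "diet:age", "mating"))
    np.testing.assert_array_equal(X[:, 0], 1.0)
    np.testing.assert_array_equal(X[:, 1], frame["age"] ** 2)
    # baseline coding: diet:age vanishes for diet-C rows regardless of age
    np.testing.assert_array_equal(X[:2, 2], 0.0)
    np.testing.assert_array_equal(X[2:, 2], frame["age"][2:])
    np.testing.assert_array_equal(X[:, 3], [0.0, 0.0, 1.0, 1.0])
    assert y.tolist() == frame["calling_s"].tolist()
    assert groups.tolist() == frame["id"].tolist()


def test_unknown_term_is_a_configuration_error():
    with pytest.raises(ConfigurationError, match="unknown model term"):
        build_design(_toy_frame(), ("intercept", "mass"))


def _simulate_lmm(n_groups, per_group, beta, sigma_u, sigma_e, seed):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), per_group)
    X = np.column_stack([np.ones(g.size), rng.normal(size=g.size)])
    y = X @ beta + rng.normal(0, sigma_u, n_groups)[g] + rng.normal(0, sigma_e, g.size)
    return X, y, g


def _bruteforce_ml_loglik(X, y, groups):
    """Direct maximisation of the marginal Gaussian likelihood over
    (coefficients, log sigma_u, log sigma_e) — independent of the profiled
    implementation."""
    p = X.shape[1]

    def nll(params):
        beta, log_su, log_se = params[:p], params[p], params[p + 1]
        su2, se2 = np.exp(2 * log_su), np.exp(2 * log_se)
        ll = 0.0
        for gid in np.unique(groups):
            m = groups == gid
            V = se2 * np.eye(m.sum()) + su2
            ll += stats.multivariate_normal.logpdf(y[m], X[m] @ beta, V)
        return -ll

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_sd = np.std(y - X @ beta0) or 1.0
    x0 = np.concatenate([beta0, [np.log(resid_sd / 2), np.log(resid_sd)]])
    best = None
    for scale in (1.0, 0.3):
        res = optimize.minimize(nll, x0 * scale if scale != 1.0 else x0,
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000, "maxfev": 20000})
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun


def test_loglik_matches_bruteforce_on_tiny_data():
    X, y, g = _simulate_lmm(3, 2, np.array([50.0, 10.0]), 5.0, 3.0, seed=1)
    fit = fit_lmm(X, y, g)
    assert fit.loglik == pytest.approx(_bruteforce_ml_loglik(X, y, g), abs=1e-6)


def test_loglik_matches_statsmodels_ml():
    import statsmodels.api as sm

    X, y, g = _simulate_lmm(40, 6, np.array([100.0, -20.0]), 30.0, 50.0, seed=2)
    fit = fit_lmm(X, y, g)
    smfit = sm.MixedLM(y, X, groups=g).fit(reml=False)
    assert fit.loglik == pytest.approx(smfit.llf, abs=1e-4)
    np.testing.assert_allclose(
        [fit.coefficients["x0"], fit.coefficients["x1"]], smfit.fe_params, rtol=1e-5
    )
    np.testing.assert_allclose(
        [fit.se["x0"], fit.se["x1"]], smfit.bse_fe, rtol=1e-3
    )
    assert fit.sigma_e == pytest.approx(np.sqrt(smfit.scale), rel=1e-3)


def test_zero_variance_group_effect_reduces_to_ols():
    X, y, g = _simulate_lmm(20, 5, np.array([10.0, 3.0]), 0.0, 2.0, seed=3)
    fit = fit_lmm(X, y, g)
    ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(
        [fit.coefficients["x0"], fit.coefficients["x1"]], ols, atol=1e-6
    )


def test_ols_constrained_aic_nesting():
    X, y, g = _simulate_lmm(30, 5, np.array([10.0, 3.0]), 8.0, 2.0, seed=4)
    fit = fit_lmm(X, y, g)
    from cricketsen.calling import _Sufficient

    _, _, _, ll0 = _Sufficient(X, y, g).gls(0.0)
    aic_ols = 2 * fit.n_params - 2 * ll0
    assert aic_ols >= fit.aic - 2.0


def test_rank_deficient_design_names_columns():
    X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
    y = np.arange(10.0)
    g = np.repeat([0, 1], 5)
    with pytest.raises(DataError, match="collinear"):
        fit_lmm(X, y, g)


def _male_frame(n_per_cell, seed):
    sizes = {k: (n_per_cell if k[0] == "male" else 0) for k in DEFAULT_HAZARDS}
    cfg = ExperimentConfig(cell_sizes=sizes, seed=seed)
    cohort, calling = generate_experiment(cfg, seed)
    return join_calling(cohort, calling)


def test_diet_age_slope_recovered_within_3_se():
    frame = _male_frame(1250, seed=5)  # 5000 males
    fit = fit_calling_model(frame, TABLE_TERMS)
    coef, se = fit.coefficients["diet:age"], fit.se["diet:age"]
    assert abs(coef - (-123.6)) < 3 * se
    assert fit.sigma_u == pytest.approx(1500.0, rel=0.15)
    assert fit.sigma_e == pytest.approx(3000.0, rel=0.05)


def test_model_comparison_prefers_true_diet_age_term():
    without = tuple(t for t in TABLE_TERMS if t not in ("diet:age", "diet:age2"))
    for seed in range(6, 11):
        frame = _male_frame(250, seed=seed)  # 1000 males
        table = compare_calling_models([list(TABLE_TERMS), list(without)], frame)
        assert table.iloc[0]["model"] == " + ".join(TABLE_TERMS)
        assert table.iloc[1]["dAIC"] > 2.0


def test_duplicate_candidates_tie():
    frame = _male_frame(60, seed=12)
    table = compare_calling_models([list(TABLE_TERMS), list(TABLE_TERMS)], frame)
    assert table["dAIC"].iloc[1] == pytest.approx(0.0, abs=1e-9)
    assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)


def test_mean_calling_ttest_runs():
    frame = _male_frame(100, seed=13)
    out = mean_calling_ttest(frame, "virgin")
    assert set(out) == {"t", "df", "p", "n_C", "n_P"}
    assert 0.0 <= out["p"] <= 1.0
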