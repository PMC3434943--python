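"""Closed-form hazard mathematics: identities, limits, and sampling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats

from cricketsen import (
    DomainError,
    HazardSpec,
    density,
    hazard,
    log_density,
    quantile,
    simulate_death_times,
    survival,
)

SPECS = {
    "constant": HazardSpec("constant", {"alpha": 0.01}),
    "gompertz": HazardSpec("gompertz", {"alpha": 0.0078, "beta": 0.0417}),
    "gompertz_makeham": HazardSpec(
        "gompertz_makeham", {"alpha": 0.0065, "beta": 0.0406, "c": 0.004}
    ),
    "logistic": HazardSpec("logistic", {"alpha": 0.0101, "beta": 0.0264, "s": 0.4}),
    "logistic_makeham": HazardSpec(
        "logistic_makeham", {"alpha": 0.008, "beta": 0.05, "s": 0.25, "c": 0.002}
    ),
    "weibull": HazardSpec("weibull", {"a": 0.0004, "b": 2.1}),
}


@pytest.mark.parametrize("spec", SPECS.values(), ids=SPECS.keys())
@pytest.mark.parametrize("x", [0.5, 5.0, 20.0, 60.0, 120.0])
def test_survival_equals_integrated_hazard(spec, x):
    integral, err = integrate.quad(lambda u: hazard(spec, u), 0.0, x, limit=200)
    assert np.log(survival(spec, x)) == pytest.approx(-integral, abs=1e-8 + 2 * err)


@pytest.mark.parametrize("spec", SPECS.values(), ids=SPECS.keys())
def test_quantile_and_survival_are_mutual_inverses(spec):
    p = np.array([0.001, 0.05, 0.25, 0.5, 0.75, 0.95, 0.999])
    x = quantile(spec, p)
    assert np.all(np.diff(x) > 0)
    np.testing.assert_allclose(1.0 - survival(spec, x), p, atol=1e-9)
    # and the other direction, on an age grid
    ages = np.array([1.0, 10.0, 40.0, 80.0])
    back = quantile(spec, 1.0 - np.asarray(survival(spec, ages)))
    np.testing.assert_allclose(back, ages, rtol=1e-9)


def test_gompertz_hazard_values():
    # hazard at age 0 is alpha itself
    assert hazard(HazardSpec("gompertz", {"alpha": 0.0101, "beta": 0.0264}), 0.0) == (
        pytest.approx(0.0101, abs=1e-12)
    )
    # direct evaluation of alpha*exp(beta*x) at x=50
    g = HazardSpec("gompertz", {"alpha": 0.0065, "beta": 0.0406})
    assert hazard(g, 50.0) == pytest.approx(0.04949156, abs=1e-7)


def test_survival_examples():
    for spec in SPECS.values():
        assert survival(spec, 0.0) == pytest.approx(1.0, abs=1e-12)
    g = HazardSpec("gompertz", {"alpha": 0.0078, "beta": 0.0417})
    assert survival(g, 37.14073) == pytest.approx(0.5, abs=1e-6)
    assert survival(HazardSpec("constant", {"alpha": 0.01}), 100.0) == pytest.approx(
        np.exp(-1.0), rel=1e-12
    )


def test_quantile_examples():
    g = HazardSpec("gompertz", {"alpha": 0.0078, "beta": 0.0417})
    assert quantile(g, 0.5) == pytest.approx(37.1407, abs=1e-3)
    g2 = HazardSpec("gompertz", {"alpha": 0.0065, "beta": 0.0406})
    assert quantile(g2, 0.5) == pytest.approx(41.2133, abs=1e-3)
    c = HazardSpec("constant", {"alpha": 0.01})
    assert quantile(c, 0.5) == pytest.approx(np.log(2) / 0.01, rel=1e-12)


def test_logistic_s_zero_reduces_to_gompertz():
    g = HazardSpec("gompertz", {"alpha": 0.0078, "beta": 0.0417})
    l = HazardSpec("logistic", {"alpha": 0.0078, "beta": 0.0417, "s": 0.0})
    for x in (0.0, 7.3, 33.0, 90.0):
        assert hazard(l, x) == pytest.approx(hazard(g, x), rel=1e-12)
        assert survival(l, x) == pytest.approx(survival(g, x), rel=1e-12)


def test_makeham_c_zero_reduces_to_gompertz():
    g = HazardSpec("gompertz", {"alpha": 0.01, "beta": 0.03})
    gm = HazardSpec("gompertz_makeham", {"alpha": 0.01, "beta": 0.03, "c": 0.0})
    x = np.linspace(0.0, 100.0, 11)
    np.testing.assert_allclose(hazard(gm, x), hazard(g, x), rtol=1e-12)
    np.testing.assert_allclose(survival(gm, x), survival(g, x), rtol=1e-12)


def test_gompertz_beta_to_zero_is_constant_hazard():
    g = HazardSpec("gompertz", {"alpha": 0.01, "beta": 1e-12})
    c = HazardSpec("constant", {"alpha": 0.01})
    x = np.array([0.0, 10.0, 200.0])
    np.testing.assert_allclose(survival(g, x), survival(c, x), rtol=1e-9)


def test_weibull_shape_one_is_exponential():
    w = HazardSpec("weibull", {"a": 0.015, "b": 1.0})
    c = HazardSpec("constant", {"alpha": 0.015})
    x = np.array([0.5, 4.0, 66.0])
    np.testing.assert_allclose(log_density(w, x), log_density(c, x), rtol=1e-12)


def test_log_density_at_zero_is_log_alpha():
    g = HazardSpec("gompertz", {"alpha": 0.0078, "beta": 0.0417})
    assert log_density(g, 0.0) == pytest.approx(np.log(0.0078), rel=1e-12)


@pytest.mark.parametrize("spec", SPECS.values(), ids=SPECS.keys())
def test_density_matches_cdf_derivative(spec):
    # exp(log_density) should equal d/dx [1 - S(x)] by finite differences
    h = 1e-6
    for x in (2.0, 15.0, 45.0):
        numeric = (survival(spec, x - h) - survival(spec, x + h)) / (2 * h)
        assert density(spec, x) == pytest.approx(numeric, rel=1e-5)


@pytest.mark.parametrize("spec", SPECS.values(), ids=SPECS.keys())
def test_density_integrates_to_one(spec):
    total, err = integrate.quad(lambda u: density(spec, u), 0.0, np.inf, limit=300)
    assert total == pytest.approx(1.0, abs=1e-6 + 2 * err)


def test_simulation_is_seed_deterministic():
    g = SPECS["gompertz"]
    a = simulate_death_times(g, 1000, seed=42)
    b = simulate_death_times(g, 1000, seed=42)
    np.testing.assert_array_equal(a, b)
    single = simulate_death_times(g, 1, seed=0)
    assert single.shape == (1,) and np.isfinite(single[0]) and single[0] > 0


def test_exponential_sample_mean():
    x = simulate_death_times(HazardSpec("constant", {"alpha": 0.02}), 100_000, seed=3)
    # mean 1/alpha = 50, MC standard error 50/sqrt(n) ~ 0.16
    assert np.mean(x) == pytest.approx(50.0, abs=0.8)


@pytest.mark.parametrize(
    "spec", [SPECS["gompertz"], SPECS["gompertz_makeham"], SPECS["weibull"]],
    ids=["gompertz", "gompertz_makeham", "weibull"],
)
def test_samples_pass_ks_against_generating_survival(spec):
    x = simulate_death_times(spec, 100_000, seed=17)
    res = stats.kstest(x, lambda t: 1.0 - np.asarray(survival(spec, t)))
    assert res.pvalue > 0.001


@pytest.mark.parametrize(
    "family,params,bad",
    [
        ("gompertz", {"alpha": -0.01, "beta": 0.03}, "alpha"),
        ("gompertz", {"alpha": 0.01, "beta": 0.0}, "beta"),
        ("gompertz_makeham", {"alpha": 0.01, "beta": 0.03, "c": -1.0}, "c"),
        ("weibull", {"a": 0.01, "b": -2.0}, "b"),
    ],
)
def test_invalid_parameters_name_the_field(family, params, bad):
    with pytest.raises(DomainError, match=bad):
        HazardSpec(family, params)


def test_domain_errors():
    g = SPECS["gompertz"]
    with pytest.raises(DomainError):
        hazard(g, -1.0)
    with pytest.raises(DomainError):
        quantile(g, 0.0)
    with pytest.raises(DomainError):
        quantile(g, 1.0)
    with pytest.raises(DomainError):
        HazardSpec("gamma", {"alpha": 1.0})
    with pytest.raises(DomainError):
        HazardSpec("gompertz", {"alpha": 1.0})
    with pytest.raises(DomainError):
        simulate_death_times(g, 0, seed=1)


def test_spec_json_round_trip():
    g = SPECS["logistic_makeham"]
    assert HazardSpec.from_json(g.to_json()) == g


@given(
    alpha=st.floats(1e-4, 0.1),
    beta=st.floats(1e-4, 0.2),
    x1=st.floats(0.0, 100.0),
    dx=st.floats(0.0, 50.0),
)
def test_gompertz_survival_is_a_nonincreasing_probability(alpha, beta, x1, dx):
    g = HazardSpec("gompertz", {"alpha": alpha, "beta": beta})
    s1, s2 = survival(g, x1), survival(g, x1 + dx)
    assert 0.0 <= s2 <= s1 <= 1.0
    assert hazard(g, x1) >= 0.0
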