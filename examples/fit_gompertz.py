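"""Fit a Gompertz mortality model to one treatment group by maximum
likelihood and report profile-likelihood confidence intervals.

alpha is the baseline mortality rate (hazard at adult age 0, per day) and
beta the exponential rate of ageing; the fit should recover the
generating values within sampling error.
"""

from cricketsen import (
    HazardSpec,
    IndividualRecord,
    ModelStructure,
    fit_mortality,
    simulate_death_times,
)

truth = HazardSpec("gompertz", {"alpha": 0.0075, "beta": 0.0482})  # CM females
times = simulate_death_times(truth, n=2000, seed=3)
records = [
    IndividualRecord(f"f{i}", "female", "C", "mated", t) for i, t in enumerate(times)
]

fit = fit_mortality(records, ModelStructure("gompertz"), ci="profile")
print(f"n = {fit.n_obs}, log-likelihood = {fit.loglik:.2f}, AIC = {fit.aic:.2f}")
for name, value in fit.estimates.items():
    lo, hi = fit.ci95[name]
    print(f"  {name}: {value:.4f}  (95% CI {lo:.4f}, {hi:.4f})   truth {truth[name]}")
# The intervals invert the likelihood-ratio statistic, so they are
# asymmetric on the natural scale, as mortality parameters should be.
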