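# Methods

This note records the models the package implements, the defaults it
ships, and the numerical and design choices behind them.

## Mortality models

Ages are continuous non-negative reals in days of adult life (day 0 =
eclosion into adulthood). Six hazard families are implemented with the
standard demographic parameterisations:

| family            | hazard mu(x)                                             |
|-------------------|----------------------------------------------------------|
| constant          | alpha                                                    |
| Gompertz          | alpha e^(beta x)                                         |
| Gompertz–Makeham  | c + alpha e^(beta x)                                     |
| logistic          | alpha e^(beta x) / (1 + (s alpha/beta)(e^(beta x) − 1))  |
| logistic–Makeham  | c + logistic hazard                                      |
| Weibull           | a b x^(b−1)                                              |

with survival S(x) = exp(−∫ mu), closed-form for every family (the
logistic survival is (1 + (s alpha/beta)(e^(beta x) − 1))^(−1/s)).
All parameters are strictly positive except the Makeham constant `c` and
the deceleration shape `s`, which may be zero; `s → 0` and `c = 0`
recover Gompertz exactly, and `beta < 1e-10` is routed to the
constant-hazard limit to avoid cancellation (exponentials are computed
via `expm1`/`log1p` throughout). Quantiles are closed-form where
available and solved by bracketed bisection (100 halvings) on the
cumulative hazard for the Makeham variants; random death times are
inverse-CDF draws, so identical seeds give identical cohorts.

All animals are followed to death: the likelihood has no censoring
terms, and death times are treated as exact continuous ages even though
real protocols check survival daily. The generator's `daily_rounding`
flag (ceiling to whole days) lets users quantify the resulting
discretisation bias; it is off by default.

## Maximum-likelihood fitting

Treatment structure: each animal sits in one diet (C/P) x mating
(mated/virgin) cell. A model structure names the hazard family and the
terms — diet, mating, and their interaction, under hierarchical
marginality — acting on the level parameter (Gompertz alpha) and the
shape parameter (Gompertz beta). Baseline levels are diet C and mated;
effects are multiplicative on the natural scale, i.e. additive on the
log working scale on which all optimisation runs, which keeps parameters
positive and matches the log-linearised estimation the design calls for.

Optimisation: Nelder–Mead from moment-based starting values, polished by
BFGS, with jittered restarts (default 5; the battery uses 2 plus a warm
start from the same family's no-effects optimum embedded with zero
effects). The restart stream has a fixed seed, so fits are deterministic
and — because per-cell death times are sorted before summation —
bit-identical under permutation of the input records. Cells referenced
by a structure must contain at least 2 deaths; smaller cells are a hard
data error rather than being silently dropped. For the Gompertz and
constant families the objective uses the closed-form per-cell
log-likelihood `n log alpha + beta Σt + (alpha/beta)(n − Σ e^{beta t})`
with precomputed per-cell statistics; the generic families go through
the density path. Both are cross-checked for equality in the tests.
Undefined parameter regions return a large finite penalty (1e12) so
gradient polishing never differences across infinities.

Confidence intervals: the default inverts the likelihood-ratio statistic
(profile deviance crossing the chi-square(1) 95% cutoff, solved by
Brent's method on the working scale, back-transformed). For the plain
two-parameter Gompertz fit the inner profile uses the closed-form
conditional MLE `alpha(beta) = n beta / (Σ e^{beta t} − n)`. If a
profile bound cannot be bracketed the parameter falls back to a Wald
interval on the log scale (exponentiated) with a logged warning; Wald
intervals are also available directly. Coverage of the profile
intervals is verified by simulation at n = 10,000 per cohort.

## Model battery and selection

The default battery crosses the 5 hierarchical term sets per parameter
(none; diet; mating; both; both + interaction) on alpha and beta — 25
Gompertz structures — plus the constant-hazard "no senescence" model.
Ranking is by AIC = 2k − 2ℓ (AICc behind a flag; plain AIC is the
default so results line up with the usual practice for these cohort
sizes), with Akaike weights over the converged fits; non-converged fits
are retained and flagged but excluded from the weight normalisation.
Ties go to the model with fewer parameters.

Sexes are analysed in separate batteries. The dedicated
pooled-versus-sexed comparison fits the full 8-parameter treatment
structure to each sex separately (equivalent to crossing every term with
sex) and to the pooled data, and refers twice the log-likelihood
difference to chi-square with 8 df. The constant-hazard model is treated
as non-nested in Gompertz for LRT purposes (beta = 0 is a boundary), so
family comparisons go through AIC, not the LRT.

## Lifespan summaries

Group medians use the standard even-n convention (mean of the two
central order statistics). "Maximum lifespan" is the median of the
longest-lived 10%, with the top decile of size ceil(n/10) (the rounding
convention is configurable; n = 10 uses the single maximum).
Confidence intervals are percentile bootstrap (2.5th/97.5th percentiles
of 5000 resample statistics by default), resampling within group only,
with a per-group seed stream spawned from one master seed.

## Calling-effort model

Nightly calling effort y_ij (seconds called by male i on observation
night j; the 15-h recording window bounds it by 54,000 s) follows a
Gaussian random-intercept model

    y_ij = x_ij' b + u_i + e_ij,  u_i ~ N(0, sigma_u²),  e_ij ~ N(0, sigma_e²)

with fixed effects (baseline diet C, mated): intercept, diet(P),
mating(virgin), age, lifespan, age², lifespan², diet:age, diet:age², and
age:lifespan. The lifespan and lifespan² terms absorb selective
disappearance — the population trajectory bending caused by short-lived
males dropping out. The random intercept is the model's only
within-male dependence structure; autocorrelation beyond it is not
modelled, and random slopes are not included (the reported fixed-effect
table implies an intercept-only random structure).

Estimation is full ML by variance-ratio profiling: for each
theta = sigma_u²/sigma_e², the per-group inverse (I + theta J)^{-1} =
I − theta/(1 + theta n_i) J reduces GLS to group-wise sums of X and y,
so each profile evaluation costs O(groups) regardless of the number of
rows. b and sigma_e² are closed-form at each theta; theta is optimised
on a 41-point log grid (log theta in [−12, 8]) refined by bounded
search, and compared against the theta = 0 boundary, which is a valid
optimum (plain regression) and is flagged. Fixed-effect SEs come from
sigma_e² (X'V⁻¹X)⁻¹. ML rather than REML so that AIC comparisons across
fixed-effect structures are valid; a REML flag exists for variance
reporting but its likelihood should not be fed into AIC, and the
implementation warns accordingly. The profiled log-likelihood is
verified in tests against brute-force maximisation of the full marginal
Gaussian likelihood on small datasets (1e-6 tolerance) and against an
independent mixed-model implementation at moderate size.

## Synthetic experiments

The generator reproduces the study design exactly: per-cell sample sizes
(males CV = 82, CM = 76, PV = 72, PM = 70; females CV = 71, CM = 76,
PV = 61, PM = 67), diet compositions (C: 9.33% protein / 74.66%
carbohydrate, a 1:8 ratio; P: 42/42, 1:1; both 84% total, remainder
cellulose, validated to ±0.05), Gompertz death times per cell at the
published fitted (alpha, beta), and male calling observations at ages 4,
9, 14, ... strictly below each male's lifespan, generated from the
fixed-effect table with each male's own realised lifespan as covariate —
which reproduces the selective-disappearance structure the lifespan
terms are meant to capture.

Defaults chosen where the source is silent, fixed once and documented:

- **Variance components** sigma_u = 1500 s, sigma_e = 3000 s. The
  fixed-effect table reports no variance components; these are the order
  of night-to-night and between-male variability in cricket calling
  data (a male averaging a few thousand seconds per night). Fixed-effect
  recovery is invariant to this choice.
- **Calling intercept** 0 s: the reported table lists contrasts and
  slopes only. The intercept shifts all predictions equally and does not
  affect any contrast or slope conclusion.
- **Clipping**: the generating model is linear-Gaussian, so simulated
  values can stray below 0; the `clip_calling` realism flag clips to
  [0, 54000]. Parameter-recovery analyses run unclipped, matching the
  linear model being fitted; the CLI `simulate` verb clips by default so
  its CSV output satisfies the calling schema.
- **Seed streams**: one master seed spawns independent child streams for
  death times, random intercepts, and residuals, so toggling one stream
  does not shift another.

What the generator does *not* emulate: measurement error in the calling
apparatus, non-Gaussian (zero-inflated, bounded) calling distributions,
egg laying or mass trajectories, and within-male autocorrelation beyond
the shared intercept. Passing recovery tests therefore show the
estimators are correct for the assumed model at the design's scale, not
that the model is right for any particular real dataset.

## Problem sizes used in the tests

The headline recomputations run at full scale: 200,000 simulated deaths
for the group medians, 500,000 for parameter recovery (baseline
mortality to 4 decimals, ageing rate to ±0.0005), 50,000 males for the
calling-coefficient recovery, 5000 bootstrap replicates, 500 null
simulations for likelihood-ratio calibration, and 200 replicates per
treatment cell at n = 10,000 for profile-CI coverage and bias. Some
illustrative simulation checks (battery detection of a strong diet
effect, calling model comparison, bootstrap coverage) run at reduced
replicate counts and cohort sizes chosen to demonstrate the property
cleanly; the counts are in the individual tests.

Note on coverage bands: with 200 replicates the Monte-Carlo SD of an
empirical 95% coverage proportion is ~1.5 percentage points, so a
93–97% acceptance band is only ~1.3 SD wide and a perfectly calibrated
method will occasionally land outside it for a given seed; larger
independent runs put the true coverage of the profile intervals at
~95–96% in every treatment cell.

## Known limitations

- No censoring machinery: every animal must be followed to death.
- No frailty/heterogeneity terms in the hazards; treatment cells are the
  only source of between-individual mortality structure.
- The LRT between hazard families is deliberately unsupported (boundary
  and non-nesting issues); use AIC.
- The REML path is a convenience for variance inspection, not a
  model-selection tool.
- The calling model is linear-Gaussian; heavy zero-inflation in real
  calling data would call for a different observation model.
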