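# Methods

## The model

`riiv` fits a Gaussian location–scale mixed model ("doubly
hierarchical" model) to repeated measures of a labile trait.  On the
transformed response scale, observation *i* of individual *j* in
individual-by-burst cell *k* is

    y_i ~ Normal(mu_i, sigma_i)
    mu_i      = x_mean_i' beta + u_mu[j] + v[k]
    log sigma_i = x_resid_i' gamma + u_sigma[j]

with

    v[k]                 ~ Normal(0, sigma_id_burst)
    (u_mu[j], u_sigma[j]) ~ MVN(0, Omega),
    Omega = [[sigma_id_mu^2, rho*sigma_id_mu*omega],
             [rho*sigma_id_mu*omega, omega^2]].

The mean design carries batch (0/1), Z-standardized body mass, week
centred on the middle burst, Z-standardized water temperature and a
morning/afternoon indicator; the residual design carries Z-mass and
centred week.  `u_sigma` is the residual intra-individual variability
(rIIV) effect: each individual's own residual SD is
`exp(gamma0 + ... + u_sigma[j])`, log-normally distributed across
individuals with log-scale SD `omega`.  The reduced model used for
comparison removes `u_sigma` (and with it `rho` and `Omega`); its
residual model keeps the fixed effects.

Assumptions: Gaussianity at all three levels after transformation; no
temporal autocorrelation within bursts; a common residual-SD model
across bursts (the individual-by-burst term enters the mean model
only — putting it in the residual model as well over-parameterizes a
design with ~5 assays per cell).

## Transformations

Activity counts are log-transformed and then Z-standardized; mass and
temperature are Z-standardized; week is centred on the second burst so
`beta3` is a per-week linear trend around the study midpoint.  Because
counts of line crossings can be zero, the default log is `log1p`, with
a strict `log` mode for data known positive.  The Z-standardization
uses the sample SD (ddof = 1) by default; both choices are recorded in
a `transform_record` so fitted values can be mapped back to counts.
Standardization statistics are computed once on the analysed rows
(after complete-case dropping), not per batch, since batch is a
modelled fixed effect.

## Priors

All priors are weakly informative on the Z-scale response:
Normal(0, 5) on every `beta` and `gamma`; half-Student-t(3, 0, 2.5) on
`sigma_id_mu`, `sigma_id_burst` and `omega`; LKJ(2) on `rho`, whose
2×2 density `∝ (1 − rho²)` places a mild peak on independence of the
mean and rIIV effects.  All are configurable through `PriorConfig`.

## Sampling and convergence

The joint posterior is sampled with a self-contained multinomial
no-U-turn sampler: non-centred random effects (standard-normal raws
scaled inside the density), SDs on the log scale, `rho` through
`tanh`, analytic gradients (the observation loop is JIT-compiled),
diagonal mass-matrix adaptation over expanding warmup windows, and
dual-averaging step-size adaptation to a 0.85 target acceptance.
Divergences are counted via an energy-error threshold of 1000.

The documented desk profile is 3 chains × (1000 warmup + 1000 draws),
which on the 104-individual design gives R-hat ≤ 1.005 and bulk ESS
well above 400 for every reported parameter in a few minutes on one
CPU; gradient-based samplers need far fewer iterations than the long
Gibbs-style runs historically used for this model class.  Replicated
simulation studies use a shorter profile (2 chains × (500 + 500)),
enough for stable 95% intervals.  A fit that violates R-hat < 1.01 or
ESS > 400, or records divergences, is flagged loudly
(`Posterior.converged`, a RuntimeWarning, and
`require_converged`); summaries still print so the offending
parameters can be inspected.

## Derived statistics

All closed forms are evaluated per posterior draw and summarized with
equal-tailed intervals; plug-ins at posterior means are reported
separately (the two differ for nonlinear maps, which is why a printed
CV of predictability can round differently from the plug-in value).

- repeatability of intercepts `R_int = s²/(s² + b²)`;
- short-term repeatability `R_short = (s² + b²)/(s² + b² + exp(g0)²)`;
- long-term repeatability `R_long = s²/(s² + b² + exp(g0)²)`
  (always ≤ min(R_int, R_short));
- coefficient of variation in predictability
  `CV_P = sqrt(exp(omega²) − 1)`, the CV of a log-normal with
  log-scale SD `omega`; for small `omega` it approaches `omega`.  The
  root is essential: it is what makes the interval endpoints of
  `CV_P` the monotone transform of `omega`'s endpoints;
- residual-variance fold between individuals ±k SD of rIIV,
  `exp(2·(2k·omega))` (SD scale: `exp(2k·omega)`);
- the mean–rIIV correlation, either directly from draws of `rho` or
  via `corr_from_cov`, which refuses covariances implying |r| > 1.

## Model comparison

WAIC is computed from the draws × observations matrix of pointwise
log-likelihoods: `lppd_i` by log-sum-exp, the penalty as the sample
variance (ddof = 1) of the pointwise log-likelihood across draws —
the convention of the R `loo` package; arviz uses the population
variance, and the cross-check test accounts for the difference.  The
pointwise terms condition on the individual-level random effects, so
the criterion targets within-individual prediction; a marginal
(integrated-over-individuals) focus would give different absolute
values.  Comparison SEs come from the pointwise differences (paired),
not from the two marginal SEs.

## The generator

`simulate` reproduces the burst design: `n_id` = 104 individuals,
3 bursts, 4–6 assays per (individual, burst) drawn uniformly, a 5.8%
whole-burst dropout (so ~294 of 312 cells and ~1477 assays are
expected, matching the design it emulates; every individual keeps at
least one burst), a 50/50 batch split, alternating morning/afternoon
assays, body mass ~ Normal(0.35 g, 0.08 g) per individual and water
temperature ~ Normal(26.0 °C, 0.5 °C) per assay — typical values for
adult guppies in tropical housing.  Default generating parameters are
the study-scale posterior means (see `TruthConfig`).  Covariates are
Z-standardized empirically inside the generator so the generating
coefficients mean the same thing the fitted ones do.

Two response modes: the default latent mode emits the response
directly on the model (Z-log) scale, the exact setting of the model's
assumptions and the right basis for recovery and coverage tests; count
mode inverts a log1p-and-Z transform and rounds to non-negative
integers, which is closer to real data but makes the re-transformed
response only approximately Gaussian.  What the generator does *not*
emulate: within-burst temporal autocorrelation, observer effects,
missingness mechanisms beyond whole-burst dropout.  Passing tests
therefore certify the inference machinery under the model's own
assumptions, not robustness to real-data violations of them.

## Problem sizes used in the test suite

Closed-form and oracle tests run on toy instances.  The replicated
checks use 20 simulate-and-refit replicates at the full 104-individual
design with the short-chain profile for parameter coverage, and 20
replicates at a 52-individual half design for the WAIC direction
check, where the expected gap (hundreds of WAIC points at full scale)
remains decisive.  These sizes give stable pass/fail behaviour in
minutes; scaling `SimConfig` and `MCMCSettings` up is a one-line
change.

## Numerical notes and edge cases

- `tanh`-mapped correlations saturate in floating point; |z| > 18 is
  treated as outside the support, as is |log SD| > 40.
- Repeatability of intercepts is undefined (error) when both variance
  components are zero; correlations are undefined when either SD is
  zero.
- With a single individual, fitting refuses: among-individual variance
  is not identifiable.
- Draw summaries use equal-tailed quantile intervals with NumPy's
  default interpolation; point estimates are posterior means, with
  medians also reported.
- Seeds: every stochastic entry point takes one integer seed; chains
  and replicates draw independent streams from `SeedSequence.spawn`,
  and identical seeds reproduce datasets and draws bit-for-bit.

## Known limitations

- No rIIV-of-rIIV (individual-by-burst term in the residual model),
  random slopes, multivariate responses, or Poisson observation model.
- WAIC absolute values depend on the random-effect conditioning; only
  within-focus comparisons are meaningful here.
- The ensemble of diagnostics (Shapiro–Wilk per level, per-individual
  residual-SD spread) summarizes the standard visual checks
  numerically; it is not a formal goodness-of-fit test of the joint
  model.
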