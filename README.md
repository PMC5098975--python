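# riiv — individual differences in behavioural predictability

`riiv` is a Python package for analysing *residual intra-individual
variability* (rIIV) in repeatedly measured labile traits — the
"predictability" axis of animal personality.  It was built around a
burst-design study of swimming activity in Trinidadian guppies
(~104 fish, three weekly bursts of 4–6 two-minute assays each,
~1 477 assays), and ships a generative simulator of that design so the
whole analysis runs end-to-end without the original data.

## The model

Activity counts are log- then Z-transformed and modelled as Gaussian
with a *doubly hierarchical* (location–scale) structure.  The mean
model for individual *j* in burst cell *k* is

    y_i ~ Normal(mu_jk, sigma_e_i)
    mu_jk = b0 + b1*Batch + b2*Mass + b3*Week + b4*Temp + b5*AMPM
            + ID_mu[j] + IDxBurst[k]

and the residual SD has its own log-linear model

    log sigma_e_i = g0 + g1*Mass + g2*Week + ID_sigma[j]

with `IDxBurst[k] ~ Normal(0, sigma_IDxBurst)` and the two individual
intercepts jointly multivariate normal,

    (ID_mu[j], ID_sigma[j]) ~ MVN(0, Omega),   corr = rho,

so individuals differ both in average activity (`sigma_ID_mu`) and in
how *predictable* they are (`omega`, the SD of `ID_sigma`), and the
two can covary.  Priors are weakly informative (Normal(0,5) on
coefficients, half-Student-t(3, 0, 2.5) on SDs, LKJ(2) on `rho`);
fitting is by NUTS over a non-centred parameterization with
convergence judged by split R-hat < 1.01 and ESS > 400.

From the variance components the package derives:

- `R_int = sigma_ID^2 / (sigma_ID^2 + sigma_IDxBurst^2)` — stability
  of individual mean values across bursts;
- `R_short = (sigma_ID^2 + sigma_IDxBurst^2) / (... + exp(g0)^2)` —
  within-burst (conditional) repeatability;
- `R_long = sigma_ID^2 / (sigma_ID^2 + sigma_IDxBurst^2 + exp(g0)^2)`
  — across-study (unconditional) repeatability;
- `CV_P = sqrt(exp(omega^2) - 1)` — the coefficient of variation in
  predictability (log-normal CV of the individual residual SDs);
- the fold-difference in residual variance between individuals ±k SD
  of rIIV, `exp(4*k*omega)`.

A reduced model with homogeneous residuals (no `ID_sigma`) is fitted
to the same data and compared by WAIC from the pointwise posterior
log-likelihoods.

## Worked example

```bash
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_fit_models.py --seed 1
python analysis/03_derived_statistics.py
python analysis/04_model_comparison.py
python analysis/05_diagnostics.py
```

On the seed-1 dataset (1 514 assays, 104 individuals, 302
individual-by-burst cells) the fitted full model prints, among others,

```
                 mean  lower  upper   rhat
sigma_id_mu     0.587  0.482  0.708  1.001
omega           0.404  0.334  0.479  1.004
sigma_id_burst  0.459  0.396  0.528  1.005
rho            -0.373 -0.587 -0.136  1.003
```

i.e. the generating values (0.51, 0.42, 0.46, −0.34) are recovered
inside their 95% credible intervals, and the derived statistics

```
                mean  lower  upper
R_int           0.62   0.49   0.73
R_short         0.58   0.51   0.66
R_long          0.36   0.26   0.46
CV_P            0.42   0.34   0.51
fold_ratio     26.45  14.51  46.27
rho_mean_riiv  -0.37  -0.59  -0.14
```

say that individual mean ranks are moderately stable across bursts
(`R_int`), repeatability is higher within bursts than across the study
(`R_short` > `R_long`), and individuals genuinely differ in
predictability: the least predictable individuals carry tens-of-fold
larger residual variance than the most predictable ones
(`fold_ratio`), which is exactly the violation of homogeneous-residual
mixed models that motivates the approach.  The WAIC comparison prints

```
                          waic    se  p_waic
full                    3204.6  63.2   274.0
reduced                 3598.1  81.2   216.7
delta (reduced - full)   393.4  47.8
```

a decisive gap in favour of heterogeneous predictability, while the
level-wise normality checks all pass (Shapiro–Wilk p = 0.42, 0.46,
0.06 for individual effects, individual-by-burst effects and scaled
residuals).

The same pipeline runs from a single config via
`riiv.run_pipeline({"seed": 1, "simulate": {}, ...})`, and
`analysis/06_recovery_study.py` replicates the simulate-and-refit
loop to tabulate bias, RMSE and interval coverage.

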