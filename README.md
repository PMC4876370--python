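# mlar1 — estimator comparison for multilevel AR(1) models

Intensive longitudinal data — many short time series, one per person —
are commonly described with a two-level first-order autoregression: scores
at level 1 follow

    y_{t,n} = mu_n + phi_n (y_{t-1,n} - mu_n) + e_{t,n},   e_{t,n} ~ N(0, sigma_e),

and at level 2 the person-specific means and autocorrelations scatter
around population values,

    mu_n = gamma_00 + U_{0,n},    phi_n = gamma_01 + U_{1,n},

with normal random effects of SD sigma_U0 and sigma_U1.  The population
autocorrelation gamma_01 ("inertia") is the quantity of interest for
applied researchers; how well it can be recovered from panels as small as
10 people x 10 time points depends strongly on *how* it is estimated.

`mlar1` implements, and pits against each other, the four standard
estimators:

| estimator | individual parameters | method |
|-----------|----------------------|--------|
| MLE-F | fixed (free per person) | exact stationary AR(1) maximum likelihood per series, averaged |
| MLE-R | random | REML linear mixed model with random intercept + random slope on the lagged score |
| BAY-F | fixed | per-series Bayesian fit, reference prior on phi, MCMC |
| BAY-R | random | hierarchical Bayesian model, reference prior on gamma_01, MCMC |

plus a fully seeded synthetic-panel generator, the study's outcome
measures (bias, empirical SD, SE bias, rejection rates, percentile
intervals, non-convergence/non-stationarity tallies), and a runner for the
fully crossed 40-condition design (T, N in {10, 25}; sigma_U1 in
{0.25, 0.40}; gamma_01 in -0.6…0.6).  Everything is deterministic given a
master seed.  See `docs/methods.md` for the modelling details and design
choices.

## Worked example

```python
from mlar1 import (Condition, generate_panel, fit_mle_random,
                   fit_bayes_random, MCMCSettings)

cond = Condition(T=25, N=25, gamma01=0.3, sigma_u1=0.25)
panel = generate_panel(cond, rng_seed=7)
print("true mean phi:", round(panel.phi_true.mean(), 3))

reml = fit_mle_random(panel)
print(f"MLE-R: gamma01_hat={reml.gamma01_hat:.3f} (SE {reml.se_gamma01:.3f}), "
      f"sigma_u1_hat={reml.sigma_u1_hat:.3f}, "
      f"CI=({reml.ci_gamma01[0]:.3f}, {reml.ci_gamma01[1]:.3f})")

bay, summary = fit_bayes_random(panel, settings=MCMCSettings(seed=7))
print(f"BAY-R: gamma01_hat={bay.gamma01_hat:.3f} (posterior SD {bay.se_gamma01:.3f}), "
      f"CrI=({bay.ci_gamma01[0]:.3f}, {bay.ci_gamma01[1]:.3f}), "
      f"max rhat={summary.rhat_all().max():.3f}")
```

prints

```
true mean phi: 0.303
MLE-R: gamma01_hat=0.333 (SE 0.064), sigma_u1_hat=0.260, CI=(0.201, 0.465)
BAY-R: gamma01_hat=0.342 (posterior SD 0.076), CrI=(0.189, 0.487), max rhat=1.012
```

The panel's 25 individuals were generated with autocorrelations averaging
0.303; both random-effects estimators recover the population value with an
interval comfortably covering it, and the hierarchical sampler's split-chain
R-hat of 1.01 indicates converged chains.  The same panel can be pushed
through `fit_mle_fixed` / `fit_bayes_fixed` to see the fixed-model price:
averaged per-series estimates carry a noticeably larger small-sample bias
at these series lengths.

A command-line interface mirrors the library:

```bash
mlar1 simulate --T 25 --N 25 --gamma01 0.3 --sigma-u1 0.25 --seed 7 --out panels
mlar1 fit panels/panel_T25_N25_g+0.30_s0.25_r0.csv --estimator MLE-R
mlar1 run --reps 50 --estimators MLE-F,MLE-R --out study_smoke   # reduced study
mlar1 sensitivity --reps 8 --out priors.csv                      # 9-prior grid
mlar1 report --study-dir study_smoke                             # table + figures
```

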