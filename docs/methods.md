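# Methods

## The model

For individual *n* (*n* = 1…*N*) observed at times *t* = 1…*T*, scores follow
a first-order autoregression around a person-specific mean:

    y_{t,n} = mu_n + phi_n (y_{t-1,n} - mu_n) + e_{t,n},    e_{t,n} ~ N(0, sigma_e)

with a second level describing how the person-specific parameters vary
across people:

    mu_n  = gamma_00 + U_{0,n},    U_{0,n} ~ N(0, sigma_U0)
    phi_n = gamma_01 + U_{1,n},    U_{1,n} ~ N(0, sigma_U1), phi_n in (-1, 1)

The population autocorrelation gamma_01 — "inertia" in the ecological
momentary assessment literature — is the parameter of scientific interest.
The package compares four ways of estimating it, crossing two modelling
stances (fixed: every individual estimated freely, population summaries are
averages; random: individual parameters are draws from a population
distribution) with two estimation methods (maximum likelihood; Bayesian
MCMC).

## Data generation

`datagen` draws phi_n from the normal distribution truncated and
renormalized to (-1, 1), guaranteeing stationary series; intercepts are
normal around gamma_00; innovations are standard normal.  The first
observation of each series is drawn from the stationary marginal
N(mu_n, sigma_e^2/(1 - phi_n^2)), so no burn-in period is needed and the
series is exactly stationary from t = 1.

Defaults mirror the study design: sigma_e = 1, gamma_00 = 0, T and N in
{10, 25}, gamma_01 in {-0.6, …, 0.6}, sigma_U1 in {0.25, 0.40}.  Two points
the design leaves open were fixed as follows and are exposed in the
configuration:

* **sigma_U0 = 1.0.**  The generating SD of the intercepts is never
  reported.  One is a natural scale choice — intercept heterogeneity of the
  same order as the innovation SD — and sensitivity runs showed the
  population-autocorrelation results are insensitive to sigma_U0 in
  {0, 1, 2}.
* **Innovations are drawn from N(0, 1)** (the distributional reading of
  "error set to mean 0, SD 1").  The alternative literal reading —
  empirically recentering/rescaling each series' realized innovations — is
  available as `standardize_innovations` and changes none of the study's
  conclusions in pilot runs.

Seeding: each (condition, replication) pair derives an independent
`SeedSequence` stream keyed by the master seed and the condition's
*parameter values*, so any cell reproduces identically whether run alone or
inside a grid, and adding conditions never perturbs existing ones.

## Fixed-model maximum likelihood

Each series is fitted by maximizing the exact Gaussian AR(1) likelihood
including the stationary density of the first observation.  This likelihood
diverges to -infinity as |phi| -> 1, so estimates are automatically
stationary — the defining property of an autocorrelation-specific routine.
Numerically the fit profiles mu and sigma_e out in closed form, leaving a
one-dimensional deviance in phi that is scanned on an 81-point grid and
polished with a bounded scalar minimizer (the scan plays the role of
multiple restarts; the profile is then locally smooth and unimodal).  The
SE of phi comes from the inverse observed information computed by central
finite differences in the (mu, atanh(phi), log sigma) parameterization and
delta-method-corrected to the phi scale.  Population summaries: the mean of
the individual estimates, the mean of their SEs, their sample SD (n-1), and
a t interval with df = N - 2.

The two-sided reading of the t quantile (1 - alpha/2) is used: the
hypothesis under test is two-sided (gamma_01 different from zero), so
nominal alpha = 0.05 corresponds to the 0.975 quantile.

## Random-model REML

The composite model is a lagged regression with random intercept and random
slope per individual.  The package fits it by restricted maximum likelihood
with *uncorrelated* random effects by default, matching a level-2 model
that declares no covariance between intercept and slope deviations; the
covariance can be freed with `correlation="free"` (the default behaviour of
common mixed-model software).  Empirically the two variants differ
negligibly on this design (checked directly against lme4 on pilot grids).

Implementation: with variance ratios lam = (sigma_U0^2, sigma_U1^2) /
sigma_e^2, the fixed effects and the residual variance have closed forms at
any lam, and because the random-effect design equals the fixed-effect
design ([1, y_{t-1}]), every REML quantity reduces to per-individual 2x2
cross-product matrices.  The profiled REML deviance is minimized over lam
(bounded L-BFGS-B; boundary estimates lam = 0 are legal and flagged).  The
optimum agrees with lme4's REML fit of the same specification to about
1e-5 on the fixed slope, its SE, and all variance components, including
singular fits — this cross-check is part of the test suite.  Individual
autocorrelations are predicted as fixed slope + BLUP of the random slope;
nothing constrains them to (-1, 1), and the share of predictions outside
that interval is one of the study's outcome measures.  The CI again uses
t with df = N - 2.

## Bayesian estimators

Both Bayesian fits place Berger's symmetrized reference prior on the
autocorrelation, pi(phi) = 1/(pi sqrt(1 - phi^2)) on (-1, 1) — the
objective prior for a stationary AR(1) coefficient; its log-density returns
-infinity outside the interval so samplers reject non-stationary proposals.
Hyperpriors follow the study's first prior test: N(0, 2) for location
parameters and Gamma(shape 2, rate 2) — mean 1 — for all SDs.  The
shape-rate convention is that of the study's sampling software.

* **BAY-F** samples (mu_n, phi_n, sigma_{e,n}) per individual under the
  exact stationary likelihood.  The point estimate is the posterior mean of
  phi_n; the replication-level interval is the average of the individual
  95% credible-interval bounds.
* **BAY-R** samples the joint posterior of (gamma_00, gamma_01, sigma_e,
  sigma_U0, sigma_U1, {U_{0,n}}, {phi_n}).  The level-2 distribution of
  phi_n is N(gamma_01, sigma_U1) with phi_n restricted to (-1, 1) but *not*
  renormalized over the interval.  This is the convention of
  bounded-parameter MCMC software, and it matters: renormalizing adds a
  -log Z(gamma_01, sigma_U1) term that rewards pushing the population
  center toward and beyond the boundary, and together with the reference
  prior's integrable spikes at ±1 it manufactures a spurious posterior mode
  at |gamma_01| near 1 (observed directly: a panel generated at mean 0.3
  yields a posterior pinned at 0.99 under the renormalized model, and a
  well-behaved posterior centered at 0.31 under the restricted one).  The
  likelihood conditions on each individual's first observation, as the
  composite model defines transitions only.  Point estimate: posterior mean
  of gamma_01; interval: central 95% credible interval; the rejection
  decision is that interval excluding zero.

The sampler is adaptive random-walk Metropolis: componentwise proposals for
the global parameters and vectorized elementwise proposals for the
per-individual blocks, with proposal scales tuned toward a 0.44 acceptance
rate in diminishing batches during burn-in only (so the post-burn-in chain
is a fixed Markov kernel).  Two translation moves — shifting (gamma_00,
{U_{0,n}}) in opposite directions and (gamma_01, {phi_n}) together —
decorrelate the population parameters from their individual effects; both
are ordinary symmetric-proposal Metropolis moves.  The contract is
distributional correctness, not algorithm identity: the test suite checks a
conjugate reduction against two-dimensional quadrature, the flat-likelihood
limit against its closed form, and mixing via split-chain R-hat.

One analytic point deserves note.  In the flat-likelihood limit (innovation
SD frozen far above the data scale) the exact stationary likelihood does
*not* become constant in phi: its initial term retains a sqrt(1 - phi^2)
factor, which exactly cancels the reference prior, leaving a uniform
posterior on (-1, 1).  The prior-recovery test therefore asserts
uniformity, the correct closed-form target, rather than prior recovery.

Defaults: 4 chains (the convergence diagnostic requires at least 2), 3000
iterations per chain with the first 1500 discarded.  Convergence is
summarized by the split-chain potential scale reduction factor (each chain
halved, classic between/within variance ratio over the 2C half-chains) and
bookkept as the mean R-hat plus the percentage of parameters above the
thresholds 1.05, 1.1, 1.5 and 1.7.

## Outcome measures

Per (condition, estimator) cell over R replications: bias of the
gamma_01 estimate; bias of the sigma_U1 estimate (for fixed estimators
sigma_U1 is the within-replication SD of the individual estimates); the
across-replication (empirical) SD; bias of the SE (mean reported SE minus
empirical SD; for fixed estimators the SE is the mean of individual SEs);
the empirical rejection rate (share of intervals excluding zero — the
actual type-I error when gamma_01 = 0, the power otherwise); and the
2.5th/97.5th percentile interval of the estimates.  All sample SDs use the
n-1 denominator; percentiles use linear interpolation (both conventions are
oracle-tested).  Non-convergence and non-stationarity are tallied per
individual fit/prediction — the only reading under which the published
percentages are arithmetically possible at 2000 panels of 10 individuals —
and replications whose whole fit fails are dropped from the measures and
counted.

## Problem sizes in the bundled reproduction

`scripts/acceptance.py` reruns the study's headline quantities with the
package's own choice of problem sizes: single-cell ML quantities at the
original R = 2000; the 40-cell grid at R = 500 per cell for the
variability ratios (the pooled non-stationarity share uses the first 200
replications per cell); and the MCMC convergence diagnostic on 5 datasets
in each of 8 representative conditions at the study's 3000/1500 iteration
schedule.  The test suite uses the same scaled design, plus reduced-R
checks (about 100 replications) for the Bayesian rejection rate and an
8-replication shared-panel design for the prior-sensitivity grid, where
sharing panels across prior settings removes the dominant Monte-Carlo noise
term from between-setting comparisons.

## What the generator does and does not emulate

Synthetic panels reproduce the statistical structure the estimators assume:
Gaussian innovations with homogeneous variance, normally distributed
individual effects, no missingness, no trends, covariates, or measurement
error.  Real momentary-assessment data violate several of these
(skewed scales, floor effects, unequal spacing, missed prompts), so passing
results certify estimator behaviour *under the model*, not robustness to
model misspecification.

## Known limitations

* The bias of the random-effects ML estimate shrinks with N in these runs
  by roughly 0.02 (T = 25, sigma_U1 = 0.25, gamma_01 = 0.6), while the
  original study reports a 0.05 difference in its corresponding condition;
  the direction agrees, the magnitude does not, and the discrepancy
  survives every tested reading of the generating process (sigma_U0 in
  {0, 1, 2}, standardized vs drawn innovations, correlated vs uncorrelated
  random effects — the last checked against lme4 itself).
* The bias measured against gamma_01 conflates estimator bias with the
  truncation shift: the truncated normal's mean is closer to zero than
  gamma_01 (about -0.029 at gamma_01 = 0.6, sigma_U1 = 0.25), an effect all
  four estimators inherit from the generating process.
* Heterogeneous innovation variances in the random models, covariates for
  the autocorrelation, and missing-data handling are out of scope.
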