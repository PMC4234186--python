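# Methods

## The model

`geosurv` analyses under-five mortality from survey birth histories with a
discrete-time survival model on a monthly grid. Each live birth contributes
one Bernoulli trial per completed month of life up to 60 months
(person-period expansion); `y_it = 1` in the month a death occurred and 0
otherwise. The monthly hazard is modelled on the logit scale by a
structured additive predictor

    logit h_it = beta0 + w_i' gamma + f0(t) + f_age(a_i) + f_str(s_i) + f_unstr(s_i)

where

- `w_i` are indicator-coded categorical covariates (residence, sex,
  preceding birth interval, antenatal care, place of delivery, household
  wealth, maternal education, marital status), each with a fixed reference
  level so that `exp(gamma)` is a posterior odds ratio against that
  reference;
- `f0(t)` is a penalised cubic B-spline smooth of age-in-months (the
  baseline hazard), `f_age` the same for mother's age at the child's birth;
  both carry second-order random-walk (RW2) priors on their coefficients,
  so constants and linear trends are unpenalised and the smoothing variance
  `tau^2` charges curvature only;
- `f_str` is an intrinsic-CAR (ICAR) field over the 11 pre-2015 DRC
  provinces: conditionally, each province effect is Normal around the mean
  of its neighbours with variance `tau^2_str / degree`;
- `f_unstr` is an iid Normal province effect capturing purely local
  heterogeneity. The reported map quantity is the *total* residual spatial
  effect `f_str + f_unstr`.

Deaths reported at 60 months or later are not under-five deaths and are
treated as censored at 60. Censored children contribute only fully observed
months (no half-interval convention).

## Priors and identifiability

Intercept and fixed effects get Gaussian priors with precision 1e-6
(effectively diffuse while keeping every full conditional proper). Each
penalised block variance gets an Inverse-Gamma(a, b) hyperprior with
a = b = 0.001 by default; all hyperparameters are configurable via
`SmoothSpec` / `SpatialSpec`. Smooths are centered after every draw to
weighted mean zero over the observed covariate distribution, spatial
vectors to plain mean zero, with the removed constants absorbed into the
intercept — this keeps the additive decomposition identified and the
intercept interpretable, and leaves the linear predictor of each draw
unchanged.

Spline defaults: 20 equal-width knot intervals for `f0` over [0, 60]
months, 12 for `f_age` over [10, 50] years, cubic degree, penalty order 2.
These are conventional P-spline settings — generous enough that the RW2
prior, not the knot count, controls smoothness — and are config-exposed.

## Posterior computation

Sampling is by Pólya-Gamma data augmentation: given
`omega_it ~ PG(1, eta_it)`, every coefficient block has an exact Gaussian
full conditional, and every variance an exact Inverse-Gamma conditional, so
the Gibbs sampler needs no tuning. The PG(1, z) draws use Devroye's
alternating-series rejection sampler (numba-compiled; exact, not
truncated-series approximate). This augmented scheme targets the same
posterior as the IWLS-Metropolis updates traditional in structured additive
regression software; the test suite checks agreement against an
independent random-walk Metropolis sampler and a quadrature oracle on small
models.

Block updates exploit structure: covariates are constant within a child and
the baseline smooth depends only on `t`, so all sufficient statistics are
per-child, per-interval, or per-province weighted sums (`bincount`
aggregations). No dense person-period design matrix is ever formed; the
largest linear solves are of the order of a spline basis (about 23×23) or
the province count (11×11). The ICAR conditional precision gets a 1e-10
ridge (its improper constant direction is removed by centering anyway), and
variance draws are floored at 1e-10.

Run-length defaults are 12,000 iterations, 2,000 burn-in, thinning 10; an
explicit seed is mandatory and all randomness (including the per-iteration
PG seeds) derives from it, so identical data + config + seed reproduce
identical draws bit for bit.

## Reporting

- **OR tables**: point estimate `exp(mean of log-odds draws)` (the
  convention of structured-additive-regression software; the alternative
  mean-of-exp is deliberately not used), with equal-tailed 80% and 95%
  credible regions. Quantiles are interpolation-free (inverted CDF), so
  credible regions commute exactly with monotone transformations.
- **Curves**: pointwise posterior mean and equal-tailed 80% band of each
  centered smooth on a grid.
- **Maps** (tabular only): per province the posterior mean total spatial
  effect (log-odds and OR scale) and a three-class code from the sign
  pattern of its 80% interval — `higher` if the interval lies strictly
  above zero, `lower` if strictly below, else `not_significant`. In the
  usual map colouring these are black / white / grey.

## Life tables

`lifetable.u5mr` computes the synthetic-cohort 5q0: monthly discrete
hazards deaths/at-risk (censored children leave the risk set at their
censoring age), composed multiplicatively within the standard DHS age
segments [0,1), [1,3), [3,6), [6,12), [12,24), [24,36), [36,48), [48,60)
and across segments:  `5q0 = 1000 (1 - prod S_seg)`. With no censoring this
equals the empirical fraction dying before 60 months exactly. The 95% CI
uses the Greenwood (delta-method) variance of log-survival, clipped to
[0, 1000]. Computation is unweighted; survey design weights are out of
scope.

## The synthetic-data generator

The generator emulates a 2007-DRC-DHS-like cohort: ~9,000 births across 11
provinces over a five-year window. Its defaults are the study conditions:

- **Scale**: `n_children = 8,992`; the log-linearly declining baseline
  hazard (slope −0.035 per month) has its level calibrated by root-finding
  so the *expected number of observed deaths* is 1,005/8,992 ≈ 11.2% of
  births under uniform censoring. Calibration uses a fixed internal
  reference population (seed 123456789, n = 20,000) so it is deterministic
  and independent of the data seed.
- **Censoring**: interview age uniform on 0–59 completed months, as implied
  by births falling uniformly in the five-year window ("none" gives full
  follow-up, used by analytic checks).
- **Covariates**: independent draws from invented marginals (the survey's
  joint covariate distribution is not public); true log-ORs reproduce the
  *orderings* of the study's descriptive tables — rural, short preceding
  interval, home delivery, single mother, low wealth and low education all
  in excess — not its printed values.
- **Mother's age**: Beta(1.8, 3.2) scaled to 14–45 years; its true effect
  is a centered U-shape (curvature 0.15 per (decade)^2, vertex 27 years).
- **Spatial pattern**: fixed centered province effects with Maniema
  highest and Kinshasa / North-Kivu lowest, matching the study's province
  ordering; the unstructured truth is zero by default.
- **Heaping**: with probability `p_heap = 0.25`, a reported death age in
  (18, 42] months is relocated to the nearest of {24, 30, 36} (ties to the
  earlier target). This is the simplest mechanism producing the
  characteristic spikes at 2, 2.5 and 3 years of age-at-death digit
  preference; it changes reported ages only, never the death count.

What the generator does *not* emulate: cluster sampling and design weights,
household/mother-level correlation between siblings, calendar trends,
migration or conflict displacement, item nonresponse. Passing recovery
tests therefore show the estimator is correct under the model's own
assumptions at survey scale, not that those assumptions hold in the real
survey.

## Problem sizes used in checks

The automated checks run at deliberately modest sizes chosen as the
smallest that give the assertions statistical power: recovery studies use
20 replicates of n = 3,000 children (null calibration n = 1,500) with
short "smoke" chains (700 iterations, 200 burn-in), the analytic life-table
check uses a 200,000-child cohort so its ±2-per-1,000 tolerance spans ~2.4
binomial SEs, and the end-to-end pipeline run uses the full default cohort
with a 2,400-iteration chain.

## Known limitations

- The ICAR+iid hierarchy shrinks province effects toward zero when the
  data carry little spatial signal; posterior-probability maps are
  therefore conservative under a true null (far fewer than 20% of regions
  flagged at the 80% level), the familiar behaviour of BYM-type models.
  Strong true patterns are flagged reliably (see the positive-control
  test).
- Monthly intervals are the finest defensible grid for birth-history data;
  grouped variants can be built by aggregating the person-period table, but
  no coarser default is provided.
- No child- or mother-level frailty, no time-varying covariate effects, no
  survey weighting, no proper-CAR/Leroux alternatives, no model-choice
  criteria (DIC). Isolated regions (graphs with islands) are rejected for
  the structured term rather than silently handled.
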