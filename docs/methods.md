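# Methods

## Model

The observation model is a Gaussian broken-stick (change-point) regression
with random group intercepts.  For observation *i* with group *s(i)* (tree
species or genus):

```
y_i ~ Normal(lambda_i, sigma)
lambda_i = b0_{s(i)} + sum_k beta_k x_{ik} + alpha_i
alpha_i  = beta_N (N_i - CL) * 1[N_i >= CL]
b0_s ~ Normal(mu, tau)
```

`N_i` is nitrogen deposition (kg N ha⁻¹ a⁻¹), `CL` the critical load, and
the `x_{ik}` are continuous confounders.  The piecewise term is exactly
zero at `N_i = CL` on both branches, so `lambda` is continuous in
deposition; below the threshold the deposition slope is exactly zero,
above it exactly `beta_N`.  The boundary is assigned to the upper branch
(`>=`), which is value-irrelevant but fixed for reproducibility.  Only the
identity link and the Normal family are supported, and there is no
spatial, temporal or repeated-measures structure: these are model
assumptions, not implementation shortcuts.

Two critical-load structures:

* **GLOBAL_CL**: a single scalar `CL` for all groups.
* **GROUP_CL**: `CL_s ~ Normal(cl_mu, cl_tau)` per group — the direct
  analogue of giving the change point a random intercept in a non-linear
  mixed model.  The headline estimate under this variant is the posterior
  of `cl_mu`.  With one group the two variants define the same mean
  structure and likelihood; their joint priors differ by the two
  hyper-parameter terms, which is inherent to the hierarchy.

## Priors

| parameter | prior | default | rationale |
|---|---|---|---|
| `CL` (or `cl_mu`) | Normal(cl_mean, cl_sd) | Normal(10, 5) | approved range 5–15 kg N ha⁻¹ a⁻¹ for coniferous woodland: midpoint as mean, half the range as sd |
| `beta_N`, each `beta_k` | Normal(0, 2) | — | vague on the N:P-per-unit scale |
| `mu` (intercept hyper-mean) | Normal(0, 10) | — | weakly informative on the response scale; unstated upstream, configurable |
| `tau` (intercept sd) | half-Cauchy(2.5) | — | weakly-informative scale default; configurable (half-Normal also available) |
| `sigma` (residual sd) | half-Cauchy(2.5) | — | same |
| `cl_tau` (spread of group CLs) | half-Cauchy(2.5) | — | same |

The CL prior is **not** truncated at zero by default: with weak data the
posterior legitimately places mass on negative values and the credible
interval should show it.  A `truncate_cl` flag (renormalised truncated
Normal) exists for users who want hard non-negativity; it is only
supported under GLOBAL_CL because truncation would additionally require
truncated-normal Gibbs steps for `cl_mu` in the hierarchy.

Covariates are used as supplied.  An optional centering switch subtracts
the sample means before fitting (recorded in the run log); centering moves
the intercepts, not `CL` or the slopes.

## Sampler

A Metropolis-within-Gibbs scheme with one block per parameter group:

* `CL` (GLOBAL_CL) or each `CL_s` (GROUP_CL): Gaussian random-walk
  Metropolis.  The CL/`beta_N` geometry is the hard part of this
  posterior, so each gets its own tunable proposal.
* `beta_N` and each covariate slope: Gaussian random-walk Metropolis.
* `b0_s` (jointly, vectorised) and `mu`: exact conjugate Gibbs draws —
  their full conditionals are Normal.
* `tau`, `sigma`, `cl_tau`: random-walk Metropolis on the log scale with
  the Jacobian correction, which keeps scale parameters strictly positive.
* `cl_mu` (GROUP_CL): conjugate Gibbs.

Proposal scales adapt by Robbins–Monro on the log scale (step `t^-0.6`,
target acceptance 0.44 for scalar blocks) during burn-in only and are
frozen afterwards, so the retained draws come from a fixed Markov kernel.
Each chain starts from an independent joint prior draw (sub-seed
`seed + chain`), giving over-dispersed starts for an honest Gelman–Rubin
check; initialization retries up to 100 prior draws if the log posterior
is non-finite and reports the offending term otherwise.

The default protocol is 2 chains × 100 000 iterations, 50 000 burn-in,
thinning 2 (25 000 retained per chain).  A desk-scale profile
(2 × 10 000, burn-in 5 000, thin 2) is provided for tests and quick
exploration; it is the profile used throughout the test suite and for the
replicate studies in `scripts/acceptance.py`, while single headline fits
there use the full protocol.  Runs are bit-reproducible given (data,
priors, config).

An empty dataset (n = 0) is accepted by the sampler and turns the
posterior into the prior; this is the mechanism behind the
prior-recovery checks.  A `fixed` mapping can pin any parameter block,
which reduces the model to conjugate or low-dimensional cases with known
posteriors — the basis of the closed-form and grid-oracle tests.

Known limitation: when `beta_N ≈ 0` the likelihood carries almost no
information about `CL` and its posterior is flat/multi-modal; the sampler
explores it as-is, with no tempering.  This is visible as prior-dominated
CL posteriors on tiny datasets.

## Diagnostics and summaries

* **R-hat**: the classical (non-split, no degrees-of-freedom correction)
  potential scale reduction factor
  `sqrt(((n-1)/n * W + B/n) / W)`, matching `coda::gelman.diag`; identical
  chains give `sqrt((n-1)/n)` (slightly below 1), divergent chains ≫ 1.
  At least two chains and two draws are required; zero within-chain
  variance returns NaN with a warning.  A rank-normalized split R-hat
  (`rhat_rank`, via arviz) is available as a modern alternative but is not
  used by default.
* **Summaries**: chains are pooled; the table reports the mean, sample sd,
  and the empirical 2.5%/97.5% quantiles with linear interpolation of
  order statistics (the numpy/R default) — the quantile definition is
  fixed and tested against an independent sorting-based computation.
* **ESS**: Geyer's initial monotone positive-pair-sum estimator per chain,
  summed over chains; reported for Monte-Carlo-error assessment, never
  used for gating.
* **Bayesian R²**: per draw,
  `R2 = Var_i(lambda_i) / (Var_i(lambda_i) + sigma^2)` with the sample
  variance of the fitted values; summarized by posterior mean and 95% CI.
  Bounded in [0, 1) draw-wise.
* Trace/density material is exported as tidy tables (`tidy_draws`,
  `effect_curve`) for external plotting; no plotting code lives in the
  package.

## Synthetic-data generator

`simulate_dataset` draws deposition ~ Uniform(range), covariates ~
Normal(mean, sd), balanced-random group labels (sizes within one of each
other; a `group_weights` knob produces imbalance), group intercepts ~
Normal(mu, tau), and adds Normal(0, sigma) noise to the model mean.

The default scenario is one fixed truth intended to look like a European
conifer gradient study: n = 100 observations, 10 species, deposition
0–30 kg N ha⁻¹ a⁻¹, `CL = 10` (the centre of the approved range),
`beta_N = 0.4`, one MAT-like covariate ~ Normal(8 °C, 3 °C) with slope
0.1, intercepts ~ Normal(12, 1), residual sd 1.2.  Those choices put the
simulated N:P responses in roughly 9–23, inside the plausible 2–25 band,
and make the above-threshold signal strong without being trivial.
`recovery_scenario(seed)` is the same truth at n = 400 for replicate
recovery studies.

What the generator does **not** emulate: the spatial clustering and
country structure of real deposition fields, unbalanced and
temporally-repeated sampling, measurement error in deposition, and
non-Gaussian response tails.  Passing recovery tests therefore show the
estimator works when its assumptions hold — they do not validate the
model against real-data violations of those assumptions.

## Pinpoint screen

`pinpoint_bins` cuts deposition into fixed-width, left-closed bins
starting at 0 (default width 5, i.e. 0–5, 5–10, …) and computes Tukey
boxplot statistics per bin (quartiles by linear interpolation, whiskers at
the most extreme points within 1.5 IQR, the rest listed as outliers).
`pinpoint_shift` reports median differences between successive non-empty
bins and flags a pair either when the interquartile boxes do not overlap
(default) or when the absolute median difference exceeds a user
threshold.  The flag is explicitly descriptive: the IQR-overlap criterion
is conservative — under the default scenario the per-bin median step above
the threshold (`beta_N ×` bin width = 2.0) is smaller than the combined
quartile spread, so the default screen flags nothing there, while a
threshold of half that step (1.5) flags a pair bracketing the generating
critical load.  Neither criterion is an inference procedure.

## Numerical choices

* CSV output at 17 significant digits and `round_trip` float parsing, so
  dataset and draws files reproduce bit-for-bit.
* Proposal scales start at 0.5 (1.0 for CL) and are adapted as above;
  acceptance rates are recorded post-burn-in per block and land in
  [0.1, 0.6] on the default scenario.
* Half-Cauchy log-densities are computed in closed form; `-inf` is
  returned (never an exception) for out-of-support proposals, so
  Metropolis steps reject them cleanly.
* Quantities reported per parameter use pooled chains; summary order
  follows the sampler's parameter layout (CL block, slopes, intercepts,
  hyper-parameters, residual sd).

## Problem sizes used in tests and the acceptance script

Prior checks use 50 000 direct draws; oracle agreement uses 20 random
instances with n ≤ 10; the conjugate and grid oracles run the desk
profile on n = 25–30; the replicate coverage study is 20 fits of n = 400
at the desk profile; the convergence check runs the full-length
protocol (2 × 100 000) once on the default n = 100 scenario; the pinpoint
illustration uses n = 2000.  These sizes make the whole suite run in a
few minutes on one CPU while keeping every Monte-Carlo tolerance at ≥ 3
standard errors.
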