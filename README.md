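# critload

Hierarchical Bayesian change-point regression for estimating **empirical
critical loads of nitrogen** (CL_emp_N) from gradient data.

An empirical critical load is the atmospheric nitrogen deposition
threshold below which damaging effects on a habitat are not expected.
Gradient studies estimate it by regressing an ecological indicator — here
the foliar N:P ratio of conifer needles — on deposition across many sites,
and asking where the response starts to change.  `critload` is written for
ecologists and air-pollution scientists who want that analysis as a small,
reproducible Python library instead of a one-off JAGS/Stan script.

## The model

For site *i* with species (or genus) *s(i)*:

```
NP_i ~ Normal(lambda_i, sigma)

lambda_i = b0_{s(i)} + sum_k beta_k * X_ik + alpha_i

alpha_i  = 0                       if N_i <  CL
         = beta_N * (N_i - CL)     if N_i >= CL

b0_s ~ Normal(mu, tau)                      (random species intercepts)
```

The mean response is flat in deposition `N_i` below the critical load `CL`
and changes linearly (slope `beta_N`) above it; covariates `X_ik` (e.g.
mean annual temperature) absorb confounding.  `CL` carries an informative
prior built from the approved critical-load range for the habitat —
midpoint as mean, half the range as sd, so the 5–15 kg N ha⁻¹ a⁻¹ range
for coniferous woodland gives `CL ~ Normal(10, 5)` — and fixed effects get
vague `Normal(0, 2)` priors.

Two variants are available:

* **`GLOBAL_CL`** — one critical load shared by all species;
* **`GROUP_CL`** — a critical load per species,
  `CL_s ~ Normal(cl_mu, cl_tau)`, with the population-level `cl_mu` as the
  headline estimate.

Posterior sampling is a bespoke Metropolis-within-Gibbs sampler (adaptive
random-walk proposals, conjugate Gibbs steps for the intercept hierarchy)
following the standard protocol of 2 chains × 100 000 iterations, 50 000
burn-in, thinning 2, with convergence checked by the classical
Gelman–Rubin potential scale reduction factor and fit summarized by the
posterior mean, 95% credible interval and Bayesian R².

## Worked example

```python
import critload as cl

data = cl.simulate_dataset(cl.default_scenario())   # 100 sites, 10 species, true CL = 10
chains = cl.run_mcmc(data, cl.ModelVariant.GLOBAL_CL, cl.PriorSpec(),
                     cl.desk_profile(seed=1))
print(cl.summarize(chains).loc[["cl", "beta_N", "sigma"]].round(3))
```

prints

```
             mean     sd    q025    q975   rhat       ess
parameter
cl          8.833  0.953   6.860  10.580  1.009   310.314
beta_N      0.380  0.026   0.332   0.434  1.003   387.207
sigma       1.175  0.086   1.019   1.354  1.000  1631.377
```

The estimated critical load is 8.8 kg N ha⁻¹ a⁻¹ with 95% credible
interval (6.9, 10.6) — covering the generating value of 10 — and above it
the N:P ratio rises by 0.38 per additional kg N (truth 0.4); `rhat ≈ 1`
says the two chains agree.  The `examples/` directory holds one short
script per capability (global fit, group-varying fit, prior predictive
check, pinpoint screen); each prints the numbers it computes and a line on
what they mean.

The same workflow is available from the shell:

```bash
critload simulate --out data.csv --seed 11
critload fit --input data.csv --outdir out --seed 1
critload pinpoint --input data.csv
```

`fit` writes the draws, a summary table (Mean / SD / CI 2.5% / CI 97.5% /
R-hat), the effect-curve table behind the usual change-point plot, and a
run log with the seed and config hash; it exits with status 3 when any
R-hat ≥ 1.1 so pipelines can gate on convergence.

## Applying it to the European foliar dataset

The motivating analysis used foliar N:P ratios of 10 conifer species from
88 European forest sites (1995–2017), published separately; that file is
not bundled.  Given a CSV `foliar_np.csv` with columns `response` (N:P),
`ndep` (kg N ha⁻¹ a⁻¹), `group` (species) and `MAT`, the full-protocol
fits are:

```bash
critload fit --input foliar_np.csv --variant global_cl --approved-range 5 15 \
             --iters 100000 --burnin 50000 --thin 2 --seed 1 --outdir out_global
critload fit --input foliar_np.csv --variant group_cl  --approved-range 5 15 \
             --iters 100000 --burnin 50000 --thin 2 --seed 1 --outdir out_group
```

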