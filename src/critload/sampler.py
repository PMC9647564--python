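"""Metropolis-within-Gibbs sampler for the change-point model posterior.

The sampler updates one parameter block at a time per sweep:

* critical load CL (random-walk Metropolis; one scalar block under
  ``GLOBAL_CL``, one block per group plus conjugate/Metropolis updates of
  the hyper-parameters ``cl_mu``/``cl_tau`` under ``GROUP_CL``),
* above-CL slope ``beta_N`` and each covariate slope (random-walk
  Metropolis),
* group intercepts ``b0_s`` and their hyper-mean ``mu`` (exact conjugate
  Gibbs draws),
* group-intercept sd and residual sd (random-walk Metropolis on the log
  scale, with the Jacobian term).

Proposal scales adapt during burn-in only (Robbins-Monro on the log scale,
diminishing step ``t^-0.6``, target acceptance 0.44 per scalar block) and
are frozen afterwards, so the post-burn-in chain is a valid fixed-kernel
Markov chain.  Chains start from independent prior draws (chain ``c`` uses
sub-seed ``seed + c``), giving over-dispersed starts for honest
Gelman-Rubin diagnostics.  Given the same data, priors and config the
result is bit-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import model as _m
from .data import GradientDataset
from .model import ModelParams, ModelVariant, PriorSpec

__all__ = ["MCMCConfig", "ChainSet", "run_mcmc", "prior_sample", "desk_profile", "full_profile"]

_FIXABLE = {
    "cl",
    "cl_mu",
    "cl_group_sd",
    "beta_N",
    "slopes",
    "group_intercepts",
    "intercept_mu",
    "intercept_sd",
    "resid_sd",
}


@dataclass(frozen=True)
class MCMCConfig:
    """Chain protocol.

    Defaults are the full-length protocol: 2 parallel chains of 100000
    iterations each, the first 50000 discarded as burn-in, the remainder
    thinned by 2.  ``adapt_window`` caps proposal adaptation (always within
    burn-in); ``None`` adapts throughout burn-in.
    """

    n_chains: int = 2
    n_iter: int = 100_000
    n_burnin: int = 50_000
    thin: int = 2
    seed: int = 0
    adapt_window: int | None = None
    target_accept: float = 0.44

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required (for R-hat)")
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")
        if self.n_retained < 2:
            raise ValueError("config retains fewer than 2 draws per chain")

    @property
    def n_retained(self) -> int:
        """Retained iterations per chain: floor((n_iter - n_burnin)/thin)."""
        return (self.n_iter - self.n_burnin) // self.thin


def full_profile(seed: int = 0, **kwargs) -> MCMCConfig:
    """The full-length chain protocol (2 x 100000, burn-in 50000, thin 2)."""
    return MCMCConfig(seed=seed, **kwargs)


def desk_profile(seed: int = 0, **kwargs) -> MCMCConfig:
    """Short profile for tests and quick exploration (2 x 10000, burn-in 5000)."""
    kwargs.setdefault("n_iter", 10_000)
    kwargs.setdefault("n_burnin", 5_000)
    return MCMCConfig(seed=seed, **kwargs)


# --------------------------------------------------------------------------- #
@dataclass
class ChainSet:
    """Post-burn-in, thinned posterior (or prior) draws from several chains.

    ``draws`` has shape (n_chains, n_retained, n_parameters); parameter
    columns are named in ``parameter_names``.  ``meta`` carries per-block
    post-adaptation acceptance rates and final proposal scales.
    """

    draws: np.ndarray
    parameter_names: list[str]
    config: MCMCConfig
    dataset_fingerprint: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chains, iterations, parameters)")
        if self.draws.shape[2] != len(self.parameter_names):
            raise ValueError("parameter_names must match the last draws axis")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("non-finite values in draws")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.draws.shape[1]

    def index(self, name: str) -> int:
        try:
            return self.parameter_names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def get(self, name: str) -> np.ndarray:
        """Draws for one parameter, shape (n_chains, n_retained)."""
        return self.draws[:, :, self.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated, shape (n_chains * n_retained,)."""
        return self.get(name).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Wide table: chain, iteration, then one column per parameter."""
        c, r, p = self.draws.shape
        out = pd.DataFrame(self.draws.reshape(c * r, p), columns=self.parameter_names)
        out.insert(0, "iteration", np.tile(np.arange(r), c))
        out.insert(0, "chain", np.repeat(np.arange(c), r))
        return out


# --------------------------------------------------------------------------- #
# parameter layout
# --------------------------------------------------------------------------- #
def _layout(variant, group_labels, covariate_labels, fixed):
    """Ordered (field, names) pairs for the sampled parameters."""
    fields = []
    if variant is ModelVariant.GLOBAL_CL:
        if "cl" not in fixed:
            fields.append(("cl", ["cl"]))
    else:
        if "cl" not in fixed:
            fields.append(("cl", [f"cl[{g}]" for g in group_labels]))
        if "cl_mu" not in fixed:
            fields.append(("cl_mu", ["cl_mu"]))
        if "cl_group_sd" not in fixed:
            fields.append(("cl_group_sd", ["cl_group_sd"]))
    if "beta_N" not in fixed:
        fields.append(("beta_N", ["beta_N"]))
    if "slopes" not in fixed and covariate_labels:
        fields.append(("slopes", [f"beta[{c}]" for c in covariate_labels]))
    if "group_intercepts" not in fixed:
        fields.append(("group_intercepts", [f"b0[{g}]" for g in group_labels]))
    if "intercept_mu" not in fixed:
        fields.append(("intercept_mu", ["mu_b0"]))
    if "intercept_sd" not in fixed:
        fields.append(("intercept_sd", ["sd_b0"]))
    if "resid_sd" not in fixed:
        fields.append(("resid_sd", ["sigma"]))
    names = [n for _, ns in fields for n in ns]
    return fields, names


def _draw_prior_state(rng, variant, priors: PriorSpec, S: int, K: int, fixed: dict):
    """One joint prior draw (respecting fixed overrides), as a plain dict."""
    st = {}
    if variant is ModelVariant.GROUP_CL:
        st["cl_mu"] = fixed.get("cl_mu", rng.normal(priors.cl_mean, priors.cl_sd))
        st["cl_group_sd"] = fixed.get(
            "cl_group_sd", _m.sample_scale(rng, *priors.cl_group_sd_prior)
        )
        st["cl"] = np.asarray(
            fixed.get("cl", rng.normal(st["cl_mu"], st["cl_group_sd"], S)), dtype=float
        )
    else:
        if "cl" in fixed:
            st["cl"] = float(fixed["cl"])
        elif priors.truncate_cl:
            from scipy import stats

            a = (0.0 - priors.cl_mean) / priors.cl_sd
            st["cl"] = float(
                stats.truncnorm.rvs(
                    a, np.inf, loc=priors.cl_mean, scale=priors.cl_sd, random_state=rng
                )
            )
        else:
            st["cl"] = rng.normal(priors.cl_mean, priors.cl_sd)
    st["beta_N"] = fixed.get(
        "beta_N", rng.normal(priors.fixed_effect_mean, priors.fixed_effect_sd)
    )
    st["slopes"] = np.asarray(
        fixed.get(
            "slopes", rng.normal(priors.fixed_effect_mean, priors.fixed_effect_sd, K)
        ),
        dtype=float,
    ).reshape(K)
    m0, s0 = priors.intercept_mu_prior
    st["intercept_mu"] = fixed.get("intercept_mu", rng.normal(m0, s0))
    st["intercept_sd"] = fixed.get(
        "intercept_sd", _m.sample_scale(rng, *priors.group_sd_prior)
    )
    st["group_intercepts"] = np.asarray(
        fixed.get(
            "group_intercepts",
            rng.normal(st["intercept_mu"], st["intercept_sd"], S),
        ),
        dtype=float,
    ).reshape(S)
    st["resid_sd"] = fixed.get("resid_sd", _m.sample_scale(rng, *priors.resid_sd_prior))
    return st


def _state_params(st, variant) -> ModelParams:
    return ModelParams(
        group_intercepts=st["group_intercepts"],
        intercept_mu=st["intercept_mu"],
        intercept_sd=st["intercept_sd"],
        slopes=st["slopes"],
        slope_n=st["beta_N"],
        change_point=st["cl"],
        resid_sd=st["resid_sd"],
        cl_mu=st.get("cl_mu"),
        cl_group_sd=st.get("cl_group_sd"),
    )


# --------------------------------------------------------------------------- #
# main sampler
# --------------------------------------------------------------------------- #
def run_mcmc(
    data: GradientDataset,
    variant: ModelVariant,
    priors: PriorSpec,
    config: MCMCConfig,
    fixed: dict | None = None,
) -> ChainSet:
    """Draw from the posterior of the change-point model.

    Parameters
    ----------
    data
        Observations; an empty dataset (n = 0) makes the likelihood vanish,
        so the draws come from the joint prior.
    variant
        ``GLOBAL_CL`` or ``GROUP_CL``.
    priors, config
        Prior specification and chain protocol.
    fixed
        Optional mapping of parameter-field names (``"cl"``, ``"beta_N"``,
        ``"slopes"``, ``"group_intercepts"``, ``"intercept_mu"``,
        ``"intercept_sd"``, ``"resid_sd"``, ``"cl_mu"``, ``"cl_group_sd"``)
        to values held constant — used for conjugate-limit and grid-oracle
        reductions.  Fixed fields are not sampled and not recorded.
    """
    fixed = dict(fixed or {})
    unknown = set(fixed) - _FIXABLE
    if unknown:
        raise ValueError(f"unknown fixed parameter(s): {sorted(unknown)}")
    if variant is ModelVariant.GROUP_CL and priors.truncate_cl:
        raise ValueError("truncate_cl is only supported under GLOBAL_CL")
    fields, names = _layout(variant, data.group_labels, data.covariate_labels, fixed)
    if not names:
        raise ValueError("all parameters are fixed; nothing to sample")

    n_ret = config.n_retained
    draws = np.empty((config.n_chains, n_ret, len(names)))
    accept_rates: dict[str, list] = {}
    scales: dict[str, list] = {}
    for c in range(config.n_chains):
        rng = np.random.default_rng(config.seed + c)
        chain, acc, sc = _run_chain(data, variant, priors, config, fixed, fields, rng)
        draws[c] = chain
        for k, v in acc.items():
            accept_rates.setdefault(k, []).append(v)
        for k, v in sc.items():
            scales.setdefault(k, []).append(v)
    meta = {
        "acceptance_rates": {k: float(np.mean(v)) for k, v in accept_rates.items()},
        "proposal_scales": {k: [float(x) for x in v] for k, v in scales.items()},
        "fixed": {k: np.asarray(v).tolist() for k, v in fixed.items()},
    }
    return ChainSet(draws, names, config, data.fingerprint(), meta)


def _run_chain(data, variant, priors, config, fixed, fields, rng):
    y = data.response
    dep = data.deposition
    X = data.covariates
    g = data.group
    n, S, K = data.n, data.n_groups, data.n_covariates
    counts = np.bincount(g, minlength=S).astype(float)
    group_rows = [np.flatnonzero(g == s) for s in range(S)] if variant is ModelVariant.GROUP_CL else None
    m0, s0 = priors.intercept_mu_prior
    gfam, gscale = priors.group_sd_prior
    rfam, rscale = priors.resid_sd_prior
    cfam, cscale = priors.cl_group_sd_prior
    target = config.target_accept
    adapt_end = config.n_burnin if config.adapt_window is None else min(
        config.adapt_window, config.n_burnin
    )

    # --- initialization: prior draw with a finite log posterior ------------
    st = None
    for _ in range(100):
        cand = _draw_prior_state(rng, variant, priors, S, K, fixed)
        params = _state_params(cand, variant)
        lpost = _m.log_likelihood(params, variant, data) + _m.log_prior(
            params, variant, priors
        )
        if math.isfinite(lpost):
            st = cand
            break
    if st is None:
        ll = _m.log_likelihood(params, variant, data)
        bad = "likelihood" if not math.isfinite(ll) else "prior"
        raise RuntimeError(
            f"could not initialize a finite log posterior after 100 prior draws "
            f"(non-finite {bad} term)"
        )

    cl = st["cl"]
    beta_N = float(st["beta_N"])
    slopes = np.array(st["slopes"], dtype=float)
    b0 = np.array(st["group_intercepts"], dtype=float)
    mu = float(st["intercept_mu"])
    tau = float(st["intercept_sd"])
    sigma = float(st["resid_sd"])
    cl_mu = float(st["cl_mu"]) if variant is ModelVariant.GROUP_CL else None
    cl_tau = float(st["cl_group_sd"]) if variant is ModelVariant.GROUP_CL else None

    # --- caches -------------------------------------------------------------
    cov = X @ slopes if K else np.zeros(n)
    cl_site = cl[g] if variant is ModelVariant.GROUP_CL else cl
    relu = np.where(dep >= cl_site, dep - cl_site, 0.0)
    alpha = beta_N * relu
    b0g = b0[g]
    resid = y - b0g - cov - alpha
    SS = float(resid @ resid)

    # proposal log-scales and adaptation counters per scalar block
    lscale: dict[str, float] = {}
    if "cl" not in fixed:
        if variant is ModelVariant.GROUP_CL:
            for s in range(S):
                lscale[f"cl[{s}]"] = 0.0
        else:
            lscale["cl"] = 0.0
    if variant is ModelVariant.GROUP_CL and "cl_group_sd" not in fixed:
        lscale["cl_group_sd"] = math.log(0.5)
    if "beta_N" not in fixed:
        lscale["beta_N"] = math.log(0.5)
    if "slopes" not in fixed:
        for k in range(K):
            lscale[f"beta[{k}]"] = math.log(0.5)
    if "intercept_sd" not in fixed:
        lscale["sd_b0"] = math.log(0.5)
    if "resid_sd" not in fixed:
        lscale["sigma"] = math.log(0.5)
    adapt_n = dict.fromkeys(lscale, 0)
    acc = {k: 0 for k in lscale}
    tot = {k: 0 for k in lscale}

    def met(key, logr, adapting, post):
        """Accept/reject + Robbins-Monro adaptation; returns acceptance."""
        accept = math.log(rng.random()) < logr
        if adapting:
            adapt_n[key] += 1
            a = math.exp(min(logr, 0.0))
            lscale[key] += (a - target) / adapt_n[key] ** 0.6
        if post:
            tot[key] += 1
            acc[key] += accept
        return accept

    n_ret = config.n_retained
    out = np.empty((n_ret, sum(len(ns) for _, ns in fields)))
    slot = 0
    inv2s2 = 1.0 / (2.0 * sigma * sigma)

    for t in range(1, config.n_iter + 1):
        adapting = t <= adapt_end
        post = t > config.n_burnin

        # ---- critical load -------------------------------------------------
        if "cl" not in fixed:
            if variant is ModelVariant.GLOBAL_CL:
                cp = cl + math.exp(lscale["cl"]) * rng.standard_normal()
                dlp = float(priors.cl_logpdf(cp)) - float(priors.cl_logpdf(cl))
                if math.isfinite(dlp):
                    relu_p = np.where(dep >= cp, dep - cp, 0.0)
                    resid_p = resid + (alpha - beta_N * relu_p)
                    SS_p = float(resid_p @ resid_p)
                    logr = -(SS_p - SS) * inv2s2 + dlp
                else:
                    logr = -np.inf
                if met("cl", logr, adapting, post):
                    cl = cp
                    relu = relu_p
                    alpha = beta_N * relu
                    resid = resid_p
                    SS = SS_p
            else:
                for s in range(S):
                    idx = group_rows[s]
                    key = f"cl[{s}]"
                    cp = cl[s] + math.exp(lscale[key]) * rng.standard_normal()
                    dlp = float(
                        _m.normal_logpdf(cp, cl_mu, cl_tau)
                        - _m.normal_logpdf(cl[s], cl_mu, cl_tau)
                    )
                    if idx.size:
                        dep_s = dep[idx]
                        relu_ps = np.where(dep_s >= cp, dep_s - cp, 0.0)
                        resid_ps = resid[idx] + (alpha[idx] - beta_N * relu_ps)
                        dSS = float(resid_ps @ resid_ps - resid[idx] @ resid[idx])
                    else:
                        dSS = 0.0
                    logr = -dSS * inv2s2 + dlp
                    if met(key, logr, adapting, post):
                        cl[s] = cp
                        if idx.size:
                            relu[idx] = relu_ps
                            alpha[idx] = beta_N * relu_ps
                            resid[idx] = resid_ps
                            SS += dSS

        if variant is ModelVariant.GROUP_CL:
            # ---- cl_mu (conjugate Gibbs) ----------------------------------
            if "cl_mu" not in fixed:
                prec = S / (cl_tau * cl_tau) + 1.0 / (priors.cl_sd * priors.cl_sd)
                mean = (
                    float(np.sum(cl)) / (cl_tau * cl_tau)
                    + priors.cl_mean / (priors.cl_sd * priors.cl_sd)
                ) / prec
                cl_mu = mean + rng.standard_normal() / math.sqrt(prec)
            # ---- cl_tau (log-scale Metropolis) ----------------------------
            if "cl_group_sd" not in fixed:
                tp = cl_tau * math.exp(
                    math.exp(lscale["cl_group_sd"]) * rng.standard_normal()
                )
                logr = (
                    float(
                        np.sum(
                            _m.normal_logpdf(cl, cl_mu, tp)
                            - _m.normal_logpdf(cl, cl_mu, cl_tau)
                        )
                    )
                    + float(_m.scale_logpdf(tp, cfam, cscale))
                    - float(_m.scale_logpdf(cl_tau, cfam, cscale))
                    + math.log(tp)
                    - math.log(cl_tau)
                )
                if met("cl_group_sd", logr, adapting, post):
                    cl_tau = tp

        # ---- beta_N --------------------------------------------------------
        if "beta_N" not in fixed:
            bp = beta_N + math.exp(lscale["beta_N"]) * rng.standard_normal()
            resid_p = resid + (beta_N - bp) * relu
            SS_p = float(resid_p @ resid_p)
            logr = (
                -(SS_p - SS) * inv2s2
                + float(
                    _m.normal_logpdf(bp, priors.fixed_effect_mean, priors.fixed_effect_sd)
                    - _m.normal_logpdf(
                        beta_N, priors.fixed_effect_mean, priors.fixed_effect_sd
                    )
                )
            )
            if met("beta_N", logr, adapting, post):
                beta_N = bp
                alpha = beta_N * relu
                resid = resid_p
                SS = SS_p

        # ---- covariate slopes ----------------------------------------------
        if "slopes" not in fixed:
            for k in range(K):
                key = f"beta[{k}]"
                bk = slopes[k]
                bp = bk + math.exp(lscale[key]) * rng.standard_normal()
                xk = X[:, k]
                resid_p = resid + (bk - bp) * xk
                SS_p = float(resid_p @ resid_p)
                logr = (
                    -(SS_p - SS) * inv2s2
                    + float(
                        _m.normal_logpdf(
                            bp, priors.fixed_effect_mean, priors.fixed_effect_sd
                        )
                        - _m.normal_logpdf(
                            bk, priors.fixed_effect_mean, priors.fixed_effect_sd
                        )
                    )
                )
                if met(key, logr, adapting, post):
                    slopes[k] = bp
                    cov = cov + (bp - bk) * xk
                    resid = resid_p
                    SS = SS_p

        # ---- group intercepts (conjugate Gibbs) ----------------------------
        if "group_intercepts" not in fixed:
            r = resid + b0g
            sums = np.bincount(g, weights=r, minlength=S)
            prec = counts / (sigma * sigma) + 1.0 / (tau * tau)
            mean = (sums / (sigma * sigma) + mu / (tau * tau)) / prec
            b0 = mean + rng.standard_normal(S) / np.sqrt(prec)
            b0g = b0[g]
            resid = r - b0g
            SS = float(resid @ resid)

        # ---- intercept hyper-mean (conjugate Gibbs) ------------------------
        if "intercept_mu" not in fixed:
            prec = S / (tau * tau) + 1.0 / (s0 * s0)
            mean = (float(np.sum(b0)) / (tau * tau) + m0 / (s0 * s0)) / prec
            mu = mean + rng.standard_normal() / math.sqrt(prec)

        # ---- intercept sd (log-scale Metropolis) ---------------------------
        if "intercept_sd" not in fixed:
            tp = tau * math.exp(math.exp(lscale["sd_b0"]) * rng.standard_normal())
            logr = (
                float(
                    np.sum(
                        _m.normal_logpdf(b0, mu, tp) - _m.normal_logpdf(b0, mu, tau)
                    )
                )
                + float(_m.scale_logpdf(tp, gfam, gscale))
                - float(_m.scale_logpdf(tau, gfam, gscale))
                + math.log(tp)
                - math.log(tau)
            )
            if met("sd_b0", logr, adapting, post):
                tau = tp

        # ---- residual sd (log-scale Metropolis) ----------------------------
        if "resid_sd" not in fixed:
            sp = sigma * math.exp(math.exp(lscale["sigma"]) * rng.standard_normal())
            logr = (
                -n * (math.log(sp) - math.log(sigma))
                - SS * (1.0 / (2.0 * sp * sp) - inv2s2)
                + float(_m.scale_logpdf(sp, rfam, rscale))
                - float(_m.scale_logpdf(sigma, rfam, rscale))
                + math.log(sp)
                - math.log(sigma)
            )
            if met("sigma", logr, adapting, post):
                sigma = sp
                inv2s2 = 1.0 / (2.0 * sigma * sigma)

        # ---- record ---------------------------------------------------------
        if post and (t - config.n_burnin) % config.thin == 0 and slot < n_ret:
            pos = 0
            for fname, fnames in fields:
                w = len(fnames)
                if fname == "cl":
                    out[slot, pos : pos + w] = cl
                elif fname == "cl_mu":
                    out[slot, pos] = cl_mu
                elif fname == "cl_group_sd":
                    out[slot, pos] = cl_tau
                elif fname == "beta_N":
                    out[slot, pos] = beta_N
                elif fname == "slopes":
                    out[slot, pos : pos + w] = slopes
                elif fname == "group_intercepts":
                    out[slot, pos : pos + w] = b0
                elif fname == "intercept_mu":
                    out[slot, pos] = mu
                elif fname == "intercept_sd":
                    out[slot, pos] = tau
                elif fname == "resid_sd":
                    out[slot, pos] = sigma
                pos += w
            slot += 1

    rates = {k: (acc[k] / tot[k] if tot[k] else float("nan")) for k in acc}
    final_scales = {k: math.exp(v) for k, v in lscale.items()}
    return out, rates, final_scales


# --------------------------------------------------------------------------- #
def prior_sample(
    priors: PriorSpec,
    variant: ModelVariant,
    config: MCMCConfig,
    n_groups: int = 1,
    n_covariates: int = 0,
    group_labels: list[str] | None = None,
    covariate_labels: list[str] | None = None,
) -> ChainSet:
    """Direct Monte-Carlo draws from the joint prior, shaped as a ChainSet.

    The retained-draw count per chain follows the config exactly as in
    :func:`run_mcmc`, so the default protocol yields 2 x 25000 = 50000
    independent prior draws.  Supports prior-recovery tests and prior
    predictive checks.
    """
    group_labels = group_labels or [f"g{s + 1}" for s in range(n_groups)]
    covariate_labels = (
        covariate_labels
        if covariate_labels is not None
        else [f"x{k + 1}" for k in range(n_covariates)]
    )
    S, K = len(group_labels), len(covariate_labels)
    fields, names = _layout(variant, group_labels, covariate_labels, fixed={})
    R = config.n_retained
    draws = np.empty((config.n_chains, R, len(names)))
    m0, s0 = priors.intercept_mu_prior
    for c in range(config.n_chains):
        rng = np.random.default_rng(config.seed + c)
        cols = {}
        if variant is ModelVariant.GROUP_CL:
            cols["cl_mu"] = rng.normal(priors.cl_mean, priors.cl_sd, R)
            cols["cl_group_sd"] = _m.sample_scale(rng, *priors.cl_group_sd_prior, size=R)
            cols["cl"] = rng.normal(
                cols["cl_mu"][:, None], cols["cl_group_sd"][:, None], (R, S)
            )
        else:
            if priors.truncate_cl:
                from scipy import stats

                a = (0.0 - priors.cl_mean) / priors.cl_sd
                cols["cl"] = stats.truncnorm.rvs(
                    a, np.inf, loc=priors.cl_mean, scale=priors.cl_sd, size=R,
                    random_state=rng,
                )
            else:
                cols["cl"] = rng.normal(priors.cl_mean, priors.cl_sd, R)
        cols["beta_N"] = rng.normal(priors.fixed_effect_mean, priors.fixed_effect_sd, R)
        cols["slopes"] = rng.normal(
            priors.fixed_effect_mean, priors.fixed_effect_sd, (R, K)
        )
        cols["intercept_mu"] = rng.normal(m0, s0, R)
        cols["intercept_sd"] = _m.sample_scale(rng, *priors.group_sd_prior, size=R)
        cols["group_intercepts"] = rng.normal(
            cols["intercept_mu"][:, None], cols["intercept_sd"][:, None], (R, S)
        )
        cols["resid_sd"] = _m.sample_scale(rng, *priors.resid_sd_prior, size=R)
        pos = 0
        for fname, fnames in fields:
            w = len(fnames)
            block = np.asarray(cols[fname], dtype=float).reshape(R, -1)
            draws[c, :, pos : pos + w] = block[:, :w]
            pos += w
    return ChainSet(draws, names, config, "prior", {"kind": "prior_sample"})
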