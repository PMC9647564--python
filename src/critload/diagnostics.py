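"""Convergence diagnostics and posterior summaries.

R-hat here is the classical (non-split, no degrees-of-freedom correction)
Gelman-Rubin potential scale reduction factor,

    PSRF = sqrt( ((n-1)/n * W + B/n) / W )

with ``W`` the mean within-chain variance and ``B`` n times the variance of
the chain means — matching the behaviour of ``coda::gelman.diag``, the
diagnostic conventional in this field.  A rank-normalized split R-hat is offered as
an optional modern alternative (:func:`rhat_rank`, requires arviz).

Posterior summaries pool all chains and report the mean, sample sd and the
empirical 2.5%/97.5% quantiles (95% credible interval); quantiles use
linear interpolation of order statistics, the default in numpy/R.
Effective sample size uses Geyer's initial monotone positive sequence
estimator, summed over chains; it is reported, never used for gating.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import GradientDataset
from .model import ModelVariant
from .sampler import ChainSet

__all__ = [
    "gelman_rubin",
    "rhat_rank",
    "effective_sample_size",
    "summarize",
    "bayes_r2",
    "effect_curve",
    "tidy_draws",
]


def _psrf(x: np.ndarray) -> float:
    """Classical PSRF on an (m, n) array of chains."""
    m, n = x.shape
    if m < 2:
        raise ValueError("at least 2 chains are required")
    if n < 2:
        raise ValueError("at least 2 retained iterations per chain are required")
    W = float(np.mean(np.var(x, axis=1, ddof=1)))
    B = n * float(np.var(np.mean(x, axis=1), ddof=1))
    if W == 0.0:
        warnings.warn("zero within-chain variance; PSRF undefined", RuntimeWarning)
        return float("nan")
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def gelman_rubin(chains: ChainSet, parameter: str) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter."""
    return _psrf(chains.get(parameter))


def rhat_all(chains: ChainSet) -> dict[str, float]:
    """Classical PSRF for every parameter."""
    return {p: _psrf(chains.get(p)) for p in chains.parameter_names}


def rhat_rank(chains: ChainSet, parameter: str) -> float:
    """Rank-normalized split R-hat (modern alternative; needs arviz)."""
    import arviz as az

    return float(az.rhat(np.asarray(chains.get(parameter)), method="rank"))


def _geyer_ess(x: np.ndarray) -> float:
    """Geyer initial-monotone-sequence ESS for one chain (1-D array)."""
    n = x.size
    x = x - x.mean()
    v = float(x @ x) / n
    if v == 0.0 or n < 4:
        return float(n)
    # autocovariances via FFT
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # pair sums P_k = rho_{2k} + rho_{2k+1}; keep while positive, enforce
    # monotone non-increasing
    npair = n // 2
    pair = rho[0 : 2 * npair : 2] + rho[1 : 2 * npair : 2]
    tau = -1.0
    prev = np.inf
    for p in pair:
        if p <= 0.0:
            break
        p = min(p, prev)
        tau += 2.0 * p
        prev = p
    tau = max(tau, 1.0)
    return n / tau


def effective_sample_size(chains: ChainSet, parameter: str) -> float:
    """ESS summed over chains (Geyer initial monotone sequence per chain)."""
    x = chains.get(parameter)
    return float(sum(_geyer_ess(np.asarray(row)) for row in x))


def summarize(chains: ChainSet) -> pd.DataFrame:
    """Per-parameter posterior summary table.

    Pools all chains; returns a DataFrame indexed by parameter name with
    columns ``mean``, ``sd``, ``q025``, ``q975`` (the 95% credible
    interval), ``rhat`` and ``ess``.  Invariant to the order in which
    chains are stacked.
    """
    rows = []
    for p in chains.parameter_names:
        x = chains.get(p)
        pooled = x.reshape(-1)
        q025, q975 = np.quantile(pooled, [0.025, 0.975])
        rows.append(
            {
                "mean": float(pooled.mean()),
                "sd": float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
                "q025": float(q025),
                "q975": float(q975),
                "rhat": _psrf(x) if x.shape[0] >= 2 and x.shape[1] >= 10 else float("nan"),
                "ess": float(sum(_geyer_ess(np.asarray(r)) for r in x)),
            }
        )
    return pd.DataFrame(rows, index=pd.Index(chains.parameter_names, name="parameter"))


# --------------------------------------------------------------------------- #
def _fitted_matrix(chains: ChainSet, data: GradientDataset, variant: ModelVariant):
    """(n_draws, n_sites) matrix of fitted values and the sigma draws."""
    names = chains.parameter_names
    g = data.group
    dep = data.deposition

    def pooled(name):
        return chains.pooled(name)

    b0 = np.column_stack([pooled(f"b0[{lab}]") for lab in data.group_labels])
    sigma = pooled("sigma")
    beta_N = pooled("beta_N")
    if variant is ModelVariant.GLOBAL_CL:
        cl_site = pooled("cl")[:, None]  # (D, 1) broadcast over sites
    else:
        cl = np.column_stack([pooled(f"cl[{lab}]") for lab in data.group_labels])
        cl_site = cl[:, g]
    lam = b0[:, g]
    if data.n_covariates:
        slopes = np.column_stack(
            [pooled(f"beta[{lab}]") for lab in data.covariate_labels]
        )
        lam = lam + slopes @ data.covariates.T
    diff = dep[None, :] - cl_site
    lam = lam + beta_N[:, None] * np.where(diff >= 0, diff, 0.0)
    return lam, sigma


def bayes_r2(
    chains: ChainSet, data: GradientDataset, variant: ModelVariant
) -> tuple[float, float, float]:
    """Bayesian R-squared: posterior mean and 95% credible interval.

    For each posterior draw ``s``,

        R2_s = Var_i(lambda_i^(s)) / (Var_i(lambda_i^(s)) + sigma_s^2)

    the variance of the fitted values over itself plus the residual
    variance.  Every draw lies in [0, 1).
    """
    if data.n < 2:
        raise ValueError("Bayesian R2 needs at least 2 observations")
    lam, sigma = _fitted_matrix(chains, data, variant)
    var_fit = lam.var(axis=1, ddof=1)
    r2 = var_fit / (var_fit + sigma**2)
    q025, q975 = np.quantile(r2, [0.025, 0.975])
    return float(r2.mean()), float(q025), float(q975)


def bayes_r2_draws(
    chains: ChainSet, data: GradientDataset, variant: ModelVariant
) -> np.ndarray:
    """Per-draw Bayesian R2 values (for custom summaries or plots)."""
    if data.n < 2:
        raise ValueError("Bayesian R2 needs at least 2 observations")
    lam, sigma = _fitted_matrix(chains, data, variant)
    var_fit = lam.var(axis=1, ddof=1)
    return var_fit / (var_fit + sigma**2)


def effect_curve(
    chains: ChainSet,
    data: GradientDataset,
    variant: ModelVariant,
    n_grid: int = 101,
) -> pd.DataFrame:
    """Population-level change-point curve over a deposition grid.

    Evaluates, for each posterior draw, the expected response at the
    intercept hyper-mean with covariates held at their sample means,
    on an even deposition grid spanning [0, max observed]; under the
    group-varying variant the population critical load ``cl_mu`` is used.
    Returns a tidy table (ndep, mean, q025, q975) — the data behind the
    usual effect plot.
    """
    grid = np.linspace(0.0, float(data.deposition.max()) if data.n else 30.0, n_grid)
    mu = chains.pooled("mu_b0")
    beta_N = chains.pooled("beta_N")
    cl = chains.pooled("cl" if variant is ModelVariant.GLOBAL_CL else "cl_mu")
    lam = mu[:, None] + np.zeros((1, n_grid))
    if data.n_covariates:
        xbar = data.covariates.mean(axis=0)
        slopes = np.column_stack(
            [chains.pooled(f"beta[{lab}]") for lab in data.covariate_labels]
        )
        lam = lam + (slopes @ xbar)[:, None]
    diff = grid[None, :] - cl[:, None]
    lam = lam + beta_N[:, None] * np.where(diff >= 0, diff, 0.0)
    lo, hi = np.quantile(lam, [0.025, 0.975], axis=0)
    return pd.DataFrame(
        {"ndep": grid, "mean": lam.mean(axis=0), "q025": lo, "q975": hi}
    )


def tidy_draws(chains: ChainSet) -> pd.DataFrame:
    """Long-format draws table (chain, iteration, parameter, value).

    The input for external trace and marginal-density plotting.
    """
    wide = chains.to_frame()
    return wide.melt(
        id_vars=["chain", "iteration"], var_name="parameter", value_name="value"
    )
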