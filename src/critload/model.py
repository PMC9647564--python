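"""Change-point (broken-stick) regression model with random intercepts.

The observation model for site ``i`` with group (species) ``s(i)`` is

    y_i ~ Normal(lambda_i, sigma)
    lambda_i = b0_{s(i)} + sum_k beta_k * x_{i,k} + alpha_i
    alpha_i  = 0                      if N_i <  CL
             = beta_N * (N_i - CL)    if N_i >= CL

so the mean response is flat in deposition below the critical load CL and
changes linearly above it; the piecewise term is continuous at ``N_i = CL``.
Group intercepts are a random effect, ``b0_s ~ Normal(mu, tau)``.

Two variants are supported:

* ``GLOBAL_CL`` — one critical load shared by all groups (the classic
  random-intercept change-point model).
* ``GROUP_CL`` — a critical load per group, drawn from a common
  ``Normal(cl_mu, cl_tau)`` distribution whose mean ``cl_mu`` carries the
  informative critical-load prior; the headline estimate under this variant
  is the posterior of ``cl_mu``.

This module provides exact evaluation of the log-likelihood and log-prior;
posterior sampling lives in :mod:`critload.sampler`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .data import GradientDataset

__all__ = [
    "ModelVariant",
    "PriorSpec",
    "ModelParams",
    "prior_from_approved_range",
    "expected_response",
    "log_likelihood",
    "log_prior",
]

_LOG_2PI = math.log(2.0 * math.pi)
_SCALE_FAMILIES = ("half-cauchy", "half-normal")


class ModelVariant(enum.Enum):
    """Which critical-load structure the model uses."""

    GLOBAL_CL = "global_cl"
    GROUP_CL = "group_cl"


# --------------------------------------------------------------------------- #
# density helpers (closed forms; shared by the sampler's delta computations)
# --------------------------------------------------------------------------- #
def normal_logpdf(x, mean, sd):
    """Elementwise log Normal(mean, sd) density."""
    z = (np.asarray(x, dtype=float) - mean) / sd
    return -0.5 * _LOG_2PI - np.log(sd) - 0.5 * z * z


def scale_logpdf(x, family: str, scale: float):
    """Log density of a positive-scale prior (half-Cauchy or half-Normal)."""
    x = np.asarray(x, dtype=float)
    if family == "half-cauchy":
        with np.errstate(divide="ignore"):
            out = np.where(
                x > 0,
                math.log(2.0 / math.pi) - math.log(scale) - np.log1p((x / scale) ** 2),
                -np.inf,
            )
        return out
    if family == "half-normal":
        return np.where(
            x > 0,
            0.5 * math.log(2.0) - 0.5 * _LOG_2PI - math.log(scale) - 0.5 * (x / scale) ** 2,
            -np.inf,
        )
    raise ValueError(f"unknown scale family {family!r}; choose from {_SCALE_FAMILIES}")


def sample_scale(rng: np.random.Generator, family: str, scale: float, size=None):
    """Draw from a positive-scale prior."""
    if family == "half-cauchy":
        return scale * np.abs(rng.standard_cauchy(size))
    if family == "half-normal":
        return np.abs(rng.normal(0.0, scale, size))
    raise ValueError(f"unknown scale family {family!r}; choose from {_SCALE_FAMILIES}")


# --------------------------------------------------------------------------- #
# priors
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class PriorSpec:
    """Prior distributions for all model parameters.

    The critical load carries an informative ``Normal(cl_mean, cl_sd)``
    prior; by default mean 10 and sd 5 kg N ha^-1 a^-1, the Normal
    constructed from the approved 5-15 range for coniferous woodland
    (midpoint as mean, half the range as sd).  Fixed effects (covariate
    slopes and the above-CL slope) get vague ``Normal(0, 2)`` priors.
    Scale parameters default to weakly-informative half-Cauchy(2.5).

    ``truncate_cl`` restricts the critical load to non-negative values
    (renormalised truncated Normal).  It is off by default — the posterior
    under the global-CL variant can legitimately place mass on negative
    values — and is only supported for :attr:`ModelVariant.GLOBAL_CL`.
    """

    cl_mean: float = 10.0
    cl_sd: float = 5.0
    fixed_effect_mean: float = 0.0
    fixed_effect_sd: float = 2.0
    intercept_mu_prior: tuple[float, float] = (0.0, 10.0)
    group_sd_prior: tuple[str, float] = ("half-cauchy", 2.5)
    resid_sd_prior: tuple[str, float] = ("half-cauchy", 2.5)
    cl_group_sd_prior: tuple[str, float] = ("half-cauchy", 2.5)
    truncate_cl: bool = False

    def __post_init__(self):
        for name in ("cl_sd", "fixed_effect_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.intercept_mu_prior[1] <= 0:
            raise ValueError("intercept_mu_prior sd must be > 0")
        for name in ("group_sd_prior", "resid_sd_prior", "cl_group_sd_prior"):
            family, scale = getattr(self, name)
            if family not in _SCALE_FAMILIES:
                raise ValueError(f"{name}: unknown family {family!r}")
            if scale <= 0:
                raise ValueError(f"{name}: scale must be > 0")

    # log-density of the CL prior, with optional truncation at zero
    def cl_logpdf(self, x):
        lp = normal_logpdf(x, self.cl_mean, self.cl_sd)
        if self.truncate_cl:
            log_z = stats.norm.logsf(0.0, loc=self.cl_mean, scale=self.cl_sd)
            lp = np.where(np.asarray(x, dtype=float) >= 0, lp - log_z, -np.inf)
        return lp


def prior_from_approved_range(low: float, high: float, **kwargs) -> PriorSpec:
    """Informative critical-load prior from an approved range.

    The prior is ``Normal(mean=(low+high)/2, sd=(high-low)/2)`` — the
    approved critical load as the mean and half the range as the standard
    deviation.  The approved 5-15 kg N ha^-1 a^-1 range for coniferous
    woodland yields Normal(10, 5).  Extra keyword arguments pass through to
    :class:`PriorSpec`.
    """
    if high <= low:
        raise ValueError("approved range requires high > low")
    return PriorSpec(cl_mean=(low + high) / 2.0, cl_sd=(high - low) / 2.0, **kwargs)


# --------------------------------------------------------------------------- #
# parameters
# --------------------------------------------------------------------------- #
@dataclass
class ModelParams:
    """One full parameter state.

    ``change_point`` is a scalar under ``GLOBAL_CL`` and a length-S vector
    under ``GROUP_CL``; in the latter case ``cl_mu`` and ``cl_group_sd``
    (the mean and sd of the group critical-load distribution) must be set.
    """

    group_intercepts: np.ndarray  # b0_s, length S
    intercept_mu: float  # mu, hyper-mean of b0_s
    intercept_sd: float  # tau > 0
    slopes: np.ndarray  # beta_k, length K
    slope_n: float  # beta_N, response change per kg N above CL
    change_point: float | np.ndarray  # CL (kg N ha^-1 a^-1)
    resid_sd: float  # sigma > 0
    cl_mu: float | None = None
    cl_group_sd: float | None = None

    def __post_init__(self):
        self.group_intercepts = np.atleast_1d(np.asarray(self.group_intercepts, dtype=float))
        self.slopes = np.asarray(self.slopes, dtype=float).reshape(-1)
        if np.ndim(self.change_point) > 0:
            self.change_point = np.asarray(self.change_point, dtype=float).reshape(-1)
        if self.intercept_sd <= 0:
            raise ValueError("intercept_sd must be > 0")
        if self.resid_sd <= 0:
            raise ValueError("resid_sd must be > 0")

    @property
    def n_groups(self) -> int:
        return self.group_intercepts.shape[0]

    def copy(self) -> "ModelParams":
        return replace(
            self,
            group_intercepts=self.group_intercepts.copy(),
            slopes=self.slopes.copy(),
            change_point=np.asarray(self.change_point).copy()
            if np.ndim(self.change_point)
            else self.change_point,
        )


def _check_variant(params: ModelParams, variant: ModelVariant) -> None:
    scalar_cl = np.ndim(params.change_point) == 0
    if variant is ModelVariant.GLOBAL_CL and not scalar_cl:
        raise ValueError("GLOBAL_CL requires a scalar change_point")
    if variant is ModelVariant.GROUP_CL:
        if scalar_cl:
            raise ValueError("GROUP_CL requires a length-S change_point vector")
        if np.asarray(params.change_point).shape[0] != params.n_groups:
            raise ValueError("change_point vector length must equal the number of groups")


# --------------------------------------------------------------------------- #
# model evaluation
# --------------------------------------------------------------------------- #
def _site_cl(params: ModelParams, variant: ModelVariant, group: np.ndarray):
    if variant is ModelVariant.GLOBAL_CL:
        return params.change_point
    return np.asarray(params.change_point)[group]


def expected_response(
    params: ModelParams,
    variant: ModelVariant,
    data: GradientDataset,
    i: int | None = None,
):
    """Expected response lambda_i (all sites, or one site if ``i`` is given).

    ``lambda_i = b0_{s(i)} + sum_k beta_k x_{i,k} + alpha_i`` with
    ``alpha_i = beta_N (N_i - CL)`` for ``N_i >= CL`` and 0 below; the two
    branches agree at the change point, so lambda is continuous in N_i.
    """
    _check_variant(params, variant)
    if data.n_groups != params.n_groups:
        raise ValueError("params and data disagree on the number of groups")
    if params.slopes.shape[0] != data.n_covariates:
        raise ValueError("params and data disagree on the number of covariates")
    cl = _site_cl(params, variant, data.group)
    alpha = np.where(
        data.deposition >= cl, params.slope_n * (data.deposition - cl), 0.0
    )
    lam = params.group_intercepts[data.group] + alpha
    if data.n_covariates:
        lam = lam + data.covariates @ params.slopes
    if i is None:
        return lam
    if not 0 <= i < data.n:
        raise IndexError(f"site index {i} outside 0..{data.n - 1}")
    return float(lam[i])


def log_likelihood(
    params: ModelParams, variant: ModelVariant, data: GradientDataset
) -> float:
    """Gaussian log-likelihood sum_i log N(y_i | lambda_i, resid_sd)."""
    if params.resid_sd <= 0:
        raise ValueError("resid_sd must be > 0")
    if data.n == 0:
        return 0.0
    lam = expected_response(params, variant, data)
    return float(np.sum(normal_logpdf(data.response, lam, params.resid_sd)))


def log_prior(
    params: ModelParams, variant: ModelVariant, priors: PriorSpec
) -> float:
    """Joint log-prior density of a parameter state.

    Terms: the informative Normal prior on the critical load (on ``cl_mu``
    under GROUP_CL, with the group critical loads Normal(cl_mu, cl_tau) and
    a scale prior on cl_tau); Normal(0, 2)-type priors on every fixed effect
    (covariate slopes and beta_N); a Normal hyper-prior on the intercept
    mean; scale priors on the group-intercept sd and the residual sd; and
    Normal(mu, tau) on each group intercept.
    """
    _check_variant(params, variant)
    lp = 0.0
    # critical-load block
    if variant is ModelVariant.GLOBAL_CL:
        lp += float(priors.cl_logpdf(params.change_point))
    else:
        if params.cl_mu is None or params.cl_group_sd is None:
            raise ValueError("GROUP_CL requires cl_mu and cl_group_sd")
        if priors.truncate_cl:
            raise ValueError("truncate_cl is only supported under GLOBAL_CL")
        if params.cl_group_sd <= 0:
            return -np.inf
        lp += float(priors.cl_logpdf(params.cl_mu))
        lp += float(scale_logpdf(params.cl_group_sd, *priors.cl_group_sd_prior))
        lp += float(
            np.sum(
                normal_logpdf(params.change_point, params.cl_mu, params.cl_group_sd)
            )
        )
    # fixed effects
    lp += float(
        normal_logpdf(params.slope_n, priors.fixed_effect_mean, priors.fixed_effect_sd)
    )
    if params.slopes.size:
        lp += float(
            np.sum(
                normal_logpdf(
                    params.slopes, priors.fixed_effect_mean, priors.fixed_effect_sd
                )
            )
        )
    # intercept hierarchy
    m0, s0 = priors.intercept_mu_prior
    lp += float(normal_logpdf(params.intercept_mu, m0, s0))
    lp += float(scale_logpdf(params.intercept_sd, *priors.group_sd_prior))
    lp += float(
        np.sum(
            normal_logpdf(
                params.group_intercepts, params.intercept_mu, params.intercept_sd
            )
        )
    )
    # residual scale
    lp += float(scale_logpdf(params.resid_sd, *priors.resid_sd_prior))
    return lp
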