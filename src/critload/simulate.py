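"""Synthetic gradient datasets with the structure the model assumes.

The generator emulates a European-style foliar nutrient gradient study:
~100 observations from ~10 conifer species along a 0-30 kg N ha^-1 a^-1
deposition gradient, an N:P-like response in the 2-25 band, and one
confounding covariate (mean annual temperature).  Deposition is drawn
uniformly over the gradient (even worst-case coverage rather than the
spatially clustered distribution of real monitoring networks), group
membership is balanced by default with an imbalance knob, and there is no
repeated-measures/temporal structure — the model being emulated has no
time term.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import GradientDataset
from .model import ModelParams, ModelVariant, expected_response

__all__ = ["SimulationTruth", "simulate_dataset", "default_scenario", "recovery_scenario"]


@dataclass(frozen=True)
class SimulationTruth:
    """Generating values for a synthetic gradient dataset.

    ``change_point`` may be a scalar (shared critical load) or a tuple of
    length ``n_groups`` (group-varying critical loads).  If
    ``group_intercepts`` is None the intercepts are drawn as
    ``Normal(intercept_mu, intercept_sd)`` — deterministically per seed.
    ``group_weights`` unbalances the group sizes; None means balanced.
    """

    n_sites: int = 100
    n_groups: int = 10
    deposition_range: tuple[float, float] = (0.0, 30.0)
    intercept_mu: float = 12.0
    intercept_sd: float = 1.0
    slopes: tuple[float, ...] = (0.1,)
    covariate_means: tuple[float, ...] = (8.0,)
    covariate_sds: tuple[float, ...] = (3.0,)
    covariate_labels: tuple[str, ...] = ("MAT",)
    slope_n: float = 0.4
    change_point: float | tuple[float, ...] = 10.0
    resid_sd: float = 1.2
    group_intercepts: tuple[float, ...] | None = None
    group_weights: tuple[float, ...] | None = None
    seed: int = 42

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        lo, hi = self.deposition_range
        if not (np.isfinite(lo) and np.isfinite(hi)) or hi <= lo or lo < 0:
            raise ValueError("deposition_range must satisfy 0 <= low < high")
        if self.intercept_sd <= 0 or self.resid_sd < 0:
            raise ValueError("intercept_sd must be > 0 and resid_sd >= 0")
        k = len(self.slopes)
        if not (len(self.covariate_means) == len(self.covariate_sds) == len(self.covariate_labels) == k):
            raise ValueError("covariate slopes/means/sds/labels must share length K")
        if np.ndim(self.change_point) and len(self.change_point) != self.n_groups:
            raise ValueError("per-group change_point must have length n_groups")
        if self.group_intercepts is not None and len(self.group_intercepts) != self.n_groups:
            raise ValueError("group_intercepts must have length n_groups")
        if self.group_weights is not None:
            w = np.asarray(self.group_weights, dtype=float)
            if w.shape != (self.n_groups,) or np.any(w <= 0):
                raise ValueError("group_weights must be n_groups positive values")

    @property
    def variant(self) -> ModelVariant:
        return ModelVariant.GROUP_CL if np.ndim(self.change_point) else ModelVariant.GLOBAL_CL

    @property
    def group_labels(self) -> list[str]:
        return [f"sp{s + 1:02d}" for s in range(self.n_groups)]


def _assign_groups(rng: np.random.Generator, truth: SimulationTruth) -> np.ndarray:
    n, S = truth.n_sites, truth.n_groups
    if truth.group_weights is None:
        # balanced-random: sizes differ by at most one, order shuffled
        base = np.tile(np.arange(S), n // S + 1)[:n]
        return rng.permutation(base)
    w = np.asarray(truth.group_weights, dtype=float)
    return rng.choice(S, size=n, p=w / w.sum())


def simulate_dataset(
    truth: SimulationTruth, return_params: bool = False
) -> GradientDataset | tuple[GradientDataset, ModelParams]:
    """Draw one synthetic dataset from the generating model.

    Deposition ~ Uniform(range); covariates ~ Normal(mean, sd); group
    intercepts ~ Normal(intercept_mu, intercept_sd) unless given; the
    response is the model's expected value plus Normal(0, resid_sd) noise.
    Deterministic per ``truth.seed``.  With ``return_params`` the realised
    :class:`ModelParams` (including the drawn intercepts) come back too.
    """
    rng = np.random.default_rng(truth.seed)
    n, S = truth.n_sites, truth.n_groups
    lo, hi = truth.deposition_range
    deposition = rng.uniform(lo, hi, n)
    K = len(truth.slopes)
    covariates = rng.normal(
        np.asarray(truth.covariate_means), np.asarray(truth.covariate_sds), (n, K)
    ) if K else np.empty((n, 0))
    group = _assign_groups(rng, truth)
    if truth.group_intercepts is None:
        b0 = rng.normal(truth.intercept_mu, truth.intercept_sd, S)
    else:
        b0 = np.asarray(truth.group_intercepts, dtype=float)
    params = ModelParams(
        group_intercepts=b0,
        intercept_mu=truth.intercept_mu,
        intercept_sd=truth.intercept_sd,
        slopes=np.asarray(truth.slopes, dtype=float),
        slope_n=truth.slope_n,
        change_point=np.asarray(truth.change_point, dtype=float)
        if np.ndim(truth.change_point)
        else float(truth.change_point),
        resid_sd=truth.resid_sd if truth.resid_sd > 0 else 1.0,
        cl_mu=float(np.mean(truth.change_point)) if np.ndim(truth.change_point) else None,
        cl_group_sd=float(np.std(truth.change_point) or 1.0)
        if np.ndim(truth.change_point)
        else None,
    )
    data = GradientDataset(
        response=np.zeros(n),
        deposition=deposition,
        covariates=covariates,
        group=group,
        group_labels=truth.group_labels,
        covariate_labels=list(truth.covariate_labels),
    )
    lam = expected_response(params, truth.variant, data)
    noise = truth.resid_sd * rng.standard_normal(n) if truth.resid_sd > 0 else 0.0
    data.response = np.asarray(lam + noise, dtype=float)
    if return_params:
        return data, params
    return data


def default_scenario() -> SimulationTruth:
    """The documented default: 100 sites, 10 species, CL = 10, beta_N = 0.4.

    Shaped like the motivating study — deposition 0-30 kg N ha^-1 a^-1,
    responses centred near typical foliar N:P values — with a fixed seed,
    so every call returns the identical truth.
    """
    return SimulationTruth()


def recovery_scenario(seed: int) -> SimulationTruth:
    """Default scenario scaled to n = 400 for parameter-recovery studies."""
    return replace(default_scenario(), n_sites=400, seed=seed)
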