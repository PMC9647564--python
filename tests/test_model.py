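"""Exact-evaluation checks for the change-point model core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import critload as cl
from critload.model import ModelVariant


def _data(response, deposition, covariates=None):
    response = np.asarray(response, dtype=float)
    n = response.size
    if covariates is None:
        covariates = np.empty((n, 0))
        labels = []
    else:
        covariates = np.asarray(covariates, dtype=float).reshape(n, -1)
        labels = [f"x{k + 1}" for k in range(covariates.shape[1])]
    return cl.GradientDataset(
        response=response,
        deposition=np.asarray(deposition, dtype=float),
        covariates=covariates,
        group=np.zeros(n, dtype=int),
        group_labels=["g1"],
        covariate_labels=labels,
    )


def _params(b0=12.0, cl_=10.0, bn=0.5, slopes=(), sd=1.0, n_groups=1, **kw):
    return cl.ModelParams(
        group_intercepts=np.full(n_groups, b0),
        intercept_mu=b0,
        intercept_sd=1.0,
        slopes=np.asarray(slopes, dtype=float),
        slope_n=bn,
        change_point=cl_,
        resid_sd=sd,
        **kw,
    )


class TestExpectedResponse:
    @pytest.mark.parametrize(
        "ndep, covariates, slopes, expected",
        [
            (8.0, None, (), 12.0),  # below the change point: flat
            (10.0, None, (), 12.0),  # at the change point: continuous
            (14.0, [[2.0]], (0.3,), 14.6),  # 12 + 0.3*2 + 0.5*(14-10)
        ],
    )
    def test_piecewise_formula(self, toy_dataset, ndep, covariates, slopes, expected):
        data = toy_dataset([0.0], [ndep], covariates=covariates)
        params = _params(slopes=slopes)
        assert cl.expected_response(params, ModelVariant.GLOBAL_CL, data, 0) == pytest.approx(
            expected, abs=1e-12
        )

    @given(
        cl_=st.floats(0, 25),
        bn=st.floats(-3, 3),
        b0=st.floats(-5, 25),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_continuity_at_change_point(self, cl_, bn, b0):
        """Left and right limits at N = CL agree to machine tolerance."""
        eps = 1e-9
        data = _data([0.0, 0.0, 0.0], [max(cl_ - eps, 0.0), cl_, cl_ + eps])
        params = _params(b0=b0, cl_=cl_, bn=bn)
        lam = cl.expected_response(params, ModelVariant.GLOBAL_CL, data)
        assert abs(lam[0] - lam[1]) < 1e-6
        assert abs(lam[2] - lam[1]) < 1e-6

    def test_flat_below_linear_above(self, toy_dataset):
        """Slope in deposition is 0 below CL and exactly beta_N above."""
        dep = np.array([0.0, 3.0, 6.0, 9.0, 11.0, 15.0, 20.0])
        data = toy_dataset(np.zeros(7), dep)
        params = _params(bn=0.7)
        lam = cl.expected_response(params, ModelVariant.GLOBAL_CL, data)
        below = lam[dep < 10.0]
        assert np.all(below == below[0])
        above = lam[dep >= 10.0]
        slopes = np.diff(above) / np.diff(dep[dep >= 10.0])
        assert slopes == pytest.approx([0.7, 0.7], abs=1e-12)

    def test_index_and_variant_errors(self, toy_dataset):
        data = toy_dataset([1.0], [5.0])
        params = _params()
        with pytest.raises(IndexError):
            cl.expected_response(params, ModelVariant.GLOBAL_CL, data, 1)
        with pytest.raises(ValueError):
            cl.expected_response(params, ModelVariant.GROUP_CL, data)


class TestLogLikelihood:
    def test_single_obs_closed_form(self, toy_dataset):
        """y = lambda and sd = 1 gives -log(sqrt(2*pi))."""
        data = toy_dataset([12.0], [5.0])
        params = _params(sd=1.0)
        got = cl.log_likelihood(params, ModelVariant.GLOBAL_CL, data)
        assert got == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_invariant_to_cl_when_slope_zero(self, toy_dataset):
        data = toy_dataset([11.0, 13.0, 12.5], [2.0, 12.0, 28.0])
        base = cl.log_likelihood(_params(bn=0.0, cl_=5.0), ModelVariant.GLOBAL_CL, data)
        moved = cl.log_likelihood(_params(bn=0.0, cl_=22.0), ModelVariant.GLOBAL_CL, data)
        assert base == pytest.approx(moved, abs=1e-14)

    @pytest.mark.parametrize("variant", list(ModelVariant))
    def test_brute_force_oracle(self, variant, random_params):
        """Matches a naive per-observation scipy sum on random instances."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n, S, K = rng.integers(1, 11), rng.integers(1, 4), rng.integers(0, 3)
            params = random_params(rng, n_groups=S, n_covariates=K, variant=variant)
            data = cl.GradientDataset(
                response=rng.normal(12, 3, n),
                deposition=rng.uniform(0, 30, n),
                covariates=rng.normal(0, 1, (n, K)),
                group=rng.integers(0, S, n),
                group_labels=[f"g{s}" for s in range(S)],
                covariate_labels=[f"x{k}" for k in range(K)],
            )
            expected = 0.0
            for i in range(n):
                s = data.group[i]
                cp = params.change_point if variant is ModelVariant.GLOBAL_CL else params.change_point[s]
                lam = params.group_intercepts[s] + float(
                    data.covariates[i] @ params.slopes
                )
                if data.deposition[i] >= cp:
                    lam += params.slope_n * (data.deposition[i] - cp)
                expected += stats.norm.logpdf(data.response[i], lam, params.resid_sd)
            got = cl.log_likelihood(params, variant, data)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_rejects_nonpositive_resid_sd(self):
        with pytest.raises(ValueError):
            _params(sd=-1.0)


class TestLogPrior:
    def test_cl_at_prior_mode(self):
        """CL at the prior mean contributes the Normal(10,5) mode density."""
        params = _params(cl_=10.0, bn=0.0)
        lp_at = cl.log_prior(params, ModelVariant.GLOBAL_CL, cl.PriorSpec())
        params2 = _params(cl_=10.0, bn=0.0)
        wide = cl.PriorSpec(cl_sd=10.0)
        lp_wide = cl.log_prior(params2, ModelVariant.GLOBAL_CL, wide)
        # doubling cl_sd with CL at the mean lowers only the CL term, by log 2
        assert lp_at - lp_wide == pytest.approx(math.log(2.0), abs=1e-12)
        # and the CL term itself is the mode of Normal(10, 5)
        mode = -math.log(5.0 * math.sqrt(2 * math.pi))
        zeroed = cl.log_prior(_params(cl_=0.0, bn=0.0), ModelVariant.GLOBAL_CL, cl.PriorSpec())
        assert lp_at - zeroed == pytest.approx(
            mode - stats.norm.logpdf(0.0, 10.0, 5.0), abs=1e-12
        )

    @pytest.mark.parametrize("variant", list(ModelVariant))
    def test_brute_force_oracle(self, variant, random_params):
        """Matches an independently coded term-by-term scipy sum."""
        rng = np.random.default_rng(11)
        priors = cl.PriorSpec()
        for _ in range(20):
            S, K = rng.integers(1, 5), rng.integers(0, 3)
            params = random_params(rng, n_groups=S, n_covariates=K, variant=variant)
            expected = 0.0
            if variant is ModelVariant.GLOBAL_CL:
                expected += stats.norm.logpdf(params.change_point, 10.0, 5.0)
            else:
                expected += stats.norm.logpdf(params.cl_mu, 10.0, 5.0)
                expected += stats.halfcauchy.logpdf(params.cl_group_sd, scale=2.5)
                expected += stats.norm.logpdf(
                    params.change_point, params.cl_mu, params.cl_group_sd
                ).sum()
            expected += stats.norm.logpdf(params.slope_n, 0.0, 2.0)
            expected += stats.norm.logpdf(params.slopes, 0.0, 2.0).sum()
            expected += stats.norm.logpdf(params.intercept_mu, 0.0, 10.0)
            expected += stats.halfcauchy.logpdf(params.intercept_sd, scale=2.5)
            expected += stats.norm.logpdf(
                params.group_intercepts, params.intercept_mu, params.intercept_sd
            ).sum()
            expected += stats.halfcauchy.logpdf(params.resid_sd, scale=2.5)
            got = cl.log_prior(params, variant, priors)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_negative_cl_admissible_unless_truncated(self):
        params = _params(cl_=-3.0)
        assert math.isfinite(cl.log_prior(params, ModelVariant.GLOBAL_CL, cl.PriorSpec()))
        trunc = cl.PriorSpec(truncate_cl=True)
        assert cl.log_prior(params, ModelVariant.GLOBAL_CL, trunc) == -math.inf


class TestApprovedRangePrior:
    @pytest.mark.parametrize(
        "low, high, mean, sd",
        [(5.0, 15.0, 10.0, 5.0), (0.0, 10.0, 5.0, 5.0)],
    )
    def test_midpoint_and_half_range(self, low, high, mean, sd):
        p = cl.prior_from_approved_range(low, high)
        assert p.cl_mean == mean and p.cl_sd == sd

    @given(a=st.floats(-50, 50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_unit_sd_for_width_two(self, a):
        assert cl.prior_from_approved_range(a, a + 2.0).cl_sd == pytest.approx(1.0)

    def test_rejects_degenerate_range(self):
        with pytest.raises(ValueError):
            cl.prior_from_approved_range(15.0, 5.0)


class TestVariantReduction:
    def test_single_group_likelihoods_match(self, toy_dataset):
        """With S = 1 the two variants define the same mean structure, so
        expected responses and likelihoods agree for matched parameters.
        (The group-varying variant carries extra hyper-prior terms, so the
        full log-priors legitimately differ.)"""
        data = toy_dataset(
            [11.0, 13.0, 14.5], [4.0, 12.0, 20.0], covariates=[[1.0], [0.0], [-1.0]]
        )
        pa = _params(slopes=(0.3,))
        pb = _params(slopes=(0.3,), cl_=np.array([10.0]), cl_mu=10.0, cl_group_sd=1.0)
        lam_a = cl.expected_response(pa, ModelVariant.GLOBAL_CL, data)
        lam_b = cl.expected_response(pb, ModelVariant.GROUP_CL, data)
        assert lam_a == pytest.approx(lam_b, abs=1e-14)
        assert cl.log_likelihood(pa, ModelVariant.GLOBAL_CL, data) == pytest.approx(
            cl.log_likelihood(pb, ModelVariant.GROUP_CL, data), abs=1e-12
        )
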