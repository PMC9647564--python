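"""Sampler contracts: determinism, prior recovery, mixing, error paths."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import critload as cl
from critload.sampler import MCMCConfig


class TestConfig:
    def test_retained_count(self):
        cfg = MCMCConfig(n_iter=100, n_burnin=40, thin=4, seed=0)
        assert cfg.n_retained == 15

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_iter": 100, "n_burnin": 100},
            {"thin": 0},
            {"n_chains": 1},
            {"target_accept": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MCMCConfig(**{"n_iter": 1000, "n_burnin": 100, "seed": 0, **kwargs})


class TestDeterminism:
    def test_same_seed_bit_identical(self, default_data):
        cfg = MCMCConfig(n_iter=400, n_burnin=100, thin=2, seed=5)
        a = cl.run_mcmc(default_data, cl.ModelVariant.GLOBAL_CL, cl.PriorSpec(), cfg)
        b = cl.run_mcmc(default_data, cl.ModelVariant.GLOBAL_CL, cl.PriorSpec(), cfg)
        assert np.array_equal(a.draws, b.draws)
        assert a.parameter_names == b.parameter_names

    def test_different_seed_different_draws(self, default_data):
        a = cl.run_mcmc(
            default_data, cl.ModelVariant.GLOBAL_CL, cl.PriorSpec(),
            MCMCConfig(n_iter=400, n_burnin=100, thin=2, seed=5),
        )
        b = cl.run_mcmc(
            default_data, cl.ModelVariant.GLOBAL_CL, cl.PriorSpec(),
            MCMCConfig(n_iter=400, n_burnin=100, thin=2, seed=6),
        )
        assert not np.array_equal(a.draws, b.draws)


class TestPriorRecovery:
    def test_empty_dataset_samples_the_cl_prior(self):
        """With no observations the posterior is the prior: the CL margin
        reproduces Normal(10, 5) within Monte-Carlo error."""
        empty = cl.GradientDataset.empty()
        cfg = MCMCConfig(n_iter=24_000, n_burnin=4_000, thin=2, seed=7)
        chains = cl.run_mcmc(empty, cl.ModelVariant.GLOBAL_CL, cl.PriorSpec(), cfg)
        x = chains.pooled("cl")
        assert x.mean() == pytest.approx(10.0, abs=0.3)
        assert x.std(ddof=1) == pytest.approx(5.0, abs=0.3)

    def test_prior_sample_closed_form_quantiles(self):
        cfg = MCMCConfig(n_iter=60_000, n_burnin=10_000, thin=1, seed=19)
        ps = cl.prior_sample(cl.PriorSpec(), cl.ModelVariant.GLOBAL_CL, cfg)
        x = ps.pooled("cl")
        assert np.quantile(x, 0.025) == pytest.approx(10 - 1.96 * 5, abs=0.3)
        assert np.quantile(x, 0.975) == pytest.approx(10 + 1.96 * 5, abs=0.3)
        b = ps.pooled("beta_N")
        assert b.mean() == pytest.approx(0.0, abs=0.05)
        assert b.std(ddof=1) == pytest.approx(2.0, abs=0.05)

    def test_zeroed_likelihood_matches_direct_prior_draws(self):
        """MCMC on an empty dataset and direct prior sampling agree in
        distribution (two-sample KS, alpha = 0.01, pre-registered seeds)."""
        empty = cl.GradientDataset.empty()
        cfg = MCMCConfig(n_iter=44_000, n_burnin=4_000, thin=20, seed=23)
        mc = cl.run_mcmc(empty, cl.ModelVariant.GLOBAL_CL, cl.PriorSpec(), cfg)
        direct = cl.prior_sample(cl.PriorSpec(), cl.ModelVariant.GLOBAL_CL, cfg)
        for name in ("cl", "beta_N", "mu_b0", "sigma"):
            stat = stats.ks_2samp(mc.pooled(name), direct.pooled(name))
            assert stat.pvalue > 0.01, name

    def test_group_cl_prior_hyperparameters_recovered(self):
        empty = cl.GradientDataset.empty(group_labels=["a", "b", "c"])
        cfg = MCMCConfig(n_iter=24_000, n_burnin=4_000, thin=2, seed=29)
        chains = cl.run_mcmc(empty, cl.ModelVariant.GROUP_CL, cl.PriorSpec(), cfg)
        x = chains.pooled("cl_mu")
        assert x.mean() == pytest.approx(10.0, abs=0.4)
        assert x.std(ddof=1) == pytest.approx(5.0, abs=0.4)


class TestMixing:
    def test_acceptance_rates_in_window_after_adaptation(self, default_data):
        """Every Metropolis block settles in [0.1, 0.6] on the default data."""
        cfg = MCMCConfig(n_iter=6_000, n_burnin=3_000, thin=2, seed=31)
        chains = cl.run_mcmc(default_data, cl.ModelVariant.GLOBAL_CL, cl.PriorSpec(), cfg)
        rates = chains.meta["acceptance_rates"]
        assert rates, "no Metropolis blocks recorded"
        for block, rate in rates.items():
            assert 0.1 <= rate <= 0.6, (block, rate)

    def test_chains_from_overdispersed_starts_converge(self, default_data):
        cfg = MCMCConfig(n_iter=10_000, n_burnin=5_000, thin=2, seed=37)
        chains = cl.run_mcmc(default_data, cl.ModelVariant.GLOBAL_CL, cl.PriorSpec(), cfg)
        rhats = cl.rhat_all(chains)
        assert max(rhats.values()) < 1.1

    def test_variance_components_strictly_positive(self, default_data):
        cfg = MCMCConfig(n_iter=2_000, n_burnin=1_000, thin=2, seed=41)
        chains = cl.run_mcmc(default_data, cl.ModelVariant.GLOBAL_CL, cl.PriorSpec(), cfg)
        assert np.all(chains.get("sigma") > 0)
        assert np.all(chains.get("sd_b0") > 0)


class TestPriorDominance:
    def test_tiny_flat_dataset_leaves_cl_prior_dominant(self):
        """n = 5 observations with beta_N = 0 carry almost no change-point
        information: the CL posterior sd stays within 25% of the prior sd."""
        truth = dataclasses.replace(
            cl.default_scenario(), n_sites=5, slope_n=0.0, seed=43
        )
        data = cl.simulate_dataset(truth)
        chains = cl.run_mcmc(
            data, cl.ModelVariant.GLOBAL_CL, cl.PriorSpec(), cl.desk_profile(seed=43)
        )
        sd = chains.pooled("cl").std(ddof=1)
        assert abs(sd - 5.0) <= 0.25 * 5.0


class TestErrors:
    def test_unknown_fixed_key_rejected(self, default_data):
        with pytest.raises(ValueError, match="unknown fixed"):
            cl.run_mcmc(
                default_data, cl.ModelVariant.GLOBAL_CL, cl.PriorSpec(),
                MCMCConfig(n_iter=100, n_burnin=10, seed=0), fixed={"nope": 1.0},
            )

    def test_all_fixed_rejected(self, toy_dataset):
        data = toy_dataset([1.0, 2.0], [1.0, 2.0])
        fixed = {
            "cl": 10.0, "beta_N": 0.0, "slopes": np.empty(0),
            "group_intercepts": np.array([1.0]), "intercept_mu": 0.0,
            "intercept_sd": 1.0, "resid_sd": 1.0,
        }
        with pytest.raises(ValueError, match="nothing to sample"):
            cl.run_mcmc(
                data, cl.ModelVariant.GLOBAL_CL, cl.PriorSpec(),
                MCMCConfig(n_iter=100, n_burnin=10, seed=0), fixed=fixed,
            )

    def test_group_cl_truncation_unsupported(self, default_data):
        with pytest.raises(ValueError, match="truncate_cl"):
            cl.run_mcmc(
                default_data, cl.ModelVariant.GROUP_CL,
                cl.PriorSpec(truncate_cl=True),
                MCMCConfig(n_iter=100, n_burnin=10, seed=0),
            )
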