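import numpy as np
import pytest

import critload as cl


@pytest.fixture(scope="session")
def default_data():
    """One realisation of the documented default scenario."""
    return cl.simulate_dataset(cl.default_scenario())


@pytest.fixture
def toy_dataset():
    """Factory for small hand-controlled datasets."""

    def make(response, deposition, covariates=None, group=None, n_groups=1):
        response = np.asarray(response, dtype=float)
        n = response.size
        deposition = np.asarray(deposition, dtype=float)
        if covariates is None:
            covariates = np.empty((n, 0))
            cov_labels = []
        else:
            covariates = np.asarray(covariates, dtype=float).reshape(n, -1)
            cov_labels = [f"x{k + 1}" for k in range(covariates.shape[1])]
        if group is None:
            group = np.zeros(n, dtype=int)
        return cl.GradientDataset(
            response=response,
            deposition=deposition,
            covariates=covariates,
            group=np.asarray(group, dtype=int),
            group_labels=[f"g{s + 1}" for s in range(n_groups)],
            covariate_labels=cov_labels,
        )

    return make


@pytest.fixture
def random_params():
    """Factory for random-but-valid parameter states."""

    def make(rng, n_groups=3, n_covariates=2, variant=cl.ModelVariant.GLOBAL_CL):
        kwargs = {}
        if variant is cl.ModelVariant.GROUP_CL:
            cp = rng.normal(10, 3, n_groups)
            kwargs = {"cl_mu": rng.normal(10, 3), "cl_group_sd": rng.uniform(0.5, 3)}
        else:
            cp = rng.normal(10, 3)
        return cl.ModelParams(
            group_intercepts=rng.normal(12, 2, n_groups),
            intercept_mu=rng.normal(12, 2),
            intercept_sd=rng.uniform(0.5, 3),
            slopes=rng.normal(0, 1, n_covariates),
            slope_n=rng.normal(0, 1),
            change_point=cp,
            resid_sd=rng.uniform(0.5, 2),
            **kwargs,
        )

    return make
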