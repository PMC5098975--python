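import warnings

import numpy as np
import pytest

from riiv.data import prepare_latent
from riiv.model import MCMCSettings, fit_full, fit_reduced
from riiv.simulate import SimConfig, simulate

SMALL_MCMC = MCMCSettings(chains=2, warmup=300, draws=300)


@pytest.fixture(scope="session")
def small_sim():
    """A small heterogeneous dataset with known truth (12 individuals)."""
    config = SimConfig(n_id=12)
    df, truth = simulate(config, seed=42)
    return df, truth


@pytest.fixture(scope="session")
def small_prepared(small_sim):
    df, _ = small_sim
    return prepare_latent(df)


@pytest.fixture(scope="session")
def small_posterior(small_prepared):
    """Full-model fit on the small dataset, short chains."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fit_full(small_prepared, mcmc=SMALL_MCMC, seed=5)


@pytest.fixture(scope="session")
def small_reduced_posterior(small_prepared):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fit_reduced(small_prepared, mcmc=SMALL_MCMC, seed=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
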