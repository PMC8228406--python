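import numpy as np
import pytest

import slrr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy_dataset():
    """A small confounded dataset: 2 hidden factors, moderate noise."""
    cfg = slrr.SimulationConfig(n=100, p=40, q=30, K=2, tau=1.0, sigma_e=0.5, seed=7)
    return slrr.generate_dataset(cfg)


@pytest.fixture(scope="session")
def easy_fit(easy_dataset):
    rho, lam, _ = slrr.select_penalties(easy_dataset.Y, easy_dataset.X)
    return slrr.fit(easy_dataset.Y, easy_dataset.X, slrr.FitConfig(rho=rho, lam=lam))
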