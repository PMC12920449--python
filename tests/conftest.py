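import numpy as np
import pytest

import mesopid as m


@pytest.fixture(scope="session")
def small_population():
    return m.generate_population(40, 3000.0, 3000.0, seed=11)


@pytest.fixture(scope="session")
def small_activity(small_population):
    params = m.ActivityParams(n_frames=4000, seed=7)
    return m.generate_correlated_activity(small_population, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_joint(rng: np.random.Generator) -> np.ndarray:
    """A random 16-outcome joint distribution (Dirichlet-flat)."""
    return rng.dirichlet(np.ones(16)).reshape(2, 2, 2, 2)
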