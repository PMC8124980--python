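import numpy as np
import pytest

from attnscreen import CohortSpec, default_config, simulate_cohort


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort for unit tests (fast; default profiles)."""
    return simulate_cohort(CohortSpec(n_control=12, n_adhd=8, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
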