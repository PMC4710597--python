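import numpy as np
import pytest

from methrisk import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A moderate default-parameter cohort shared across read-only tests."""
    return generate_cohort(SimConfig(n_participants=1000, seed=20240901))


@pytest.fixture(scope="session")
def large_cohort():
    """Larger cohort for recovery-style checks."""
    return generate_cohort(SimConfig(n_participants=10000, seed=77))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
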