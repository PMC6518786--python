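import numpy as np
import pytest

from circmort import SimConfig, sample_records


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort with a mild rhythm, shared across tests."""
    return sample_records(SimConfig(n=4000, rho=0.2, mu=360.0, seed=123))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
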