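import numpy as np
import pytest

from emtprog.simulate import preset_published_cohort


@pytest.fixture(scope="session")
def published_cohort():
    """One preset synthetic cohort shared across tests (n=202, seed 0)."""
    return preset_published_cohort(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
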