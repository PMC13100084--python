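import numpy as np
import pytest

from vacpih.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def cohort405():
    """One study-sized synthetic cohort shared across tests."""
    return generate_cohort(CohortSpec(n=405, seed=1))


@pytest.fixture(scope="session")
def cohort_large():
    """A large cohort for recovery/calibration checks."""
    return generate_cohort(CohortSpec(n=20_000, seed=7, gls_missing_rate=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
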