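import numpy as np
import pytest

from brcastrat import CohortConfig, generate_cohort, synthetic_signature_matrix


@pytest.fixture(scope="session")
def signatures():
    return synthetic_signature_matrix()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration synthetic cohort, shared across tests."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
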