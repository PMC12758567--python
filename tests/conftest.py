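import numpy as np
import pytest

from microdyad.simulate import TrueParams, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Complete (no missingness) 30-dyad cohort reused across read-only tests."""
    return simulate_cohort(TrueParams(n_dyads=30, missing_rate=0.0, seed=11))


@pytest.fixture(scope="session")
def masked_cohort():
    """Default-missingness 30-dyad cohort."""
    return simulate_cohort(TrueParams(n_dyads=30, seed=12))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
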