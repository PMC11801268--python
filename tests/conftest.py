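import numpy as np
import pytest

from alistrat.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(n=150, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
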