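import numpy as np
import pytest

from binpsych.cohort import generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(20, seed=42)


@pytest.fixture(scope="session")
def big_cohort():
    return generate_cohort(20_000, seed=7)
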