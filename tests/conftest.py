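import numpy as np
import pandas as pd
import pytest

from adsubtype import CohortSpec, generate_cohort

SMALL_SIZES = {
    "HC": 60,
    "typical": 40,
    "limbic_predominant": 25,
    "hippocampal_sparing": 25,
    "no_atrophy": 25,
}


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(group_sizes=dict(SMALL_SIZES), seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the default (study-sized) group counts."""
    return generate_cohort(CohortSpec(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
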