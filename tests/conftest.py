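import numpy as np
import pytest
from hypothesis import settings

from ohtsim import sample_cohort
from ohtsim.config import default_params

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params20k():
    return default_params(n=20_000, seed=1)


@pytest.fixture(scope="session")
def cohort20k(params20k):
    return sample_cohort(params20k.cohort)


@pytest.fixture(scope="session")
def small_params():
    return default_params(n=500, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return sample_cohort(small_params.cohort)
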