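import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dwinode.models import BValueProtocol
from dwinode.synthetic import default_group_specs, sample_cohort

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol() -> BValueProtocol:
    return BValueProtocol()


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded 23/45 cohort drawn from the published summaries."""
    benign, metastatic = default_group_specs()
    return sample_cohort(benign, metastatic, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
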