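import numpy as np
import pytest
from hypothesis import settings

from mangrove_slr.synthetic_site import SiteConfig, make_site_fixture

settings.register_profile("ci", derandomize=True, max_examples=50,
                          database=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_fixture():
    """A moderately noisy synthetic site shared by read-only tests."""
    return make_site_fixture(SiteConfig(seed=7))


@pytest.fixture(scope="session")
def clean_fixture():
    """A fully deterministic (noise-free) site: generator truth is exact."""
    return make_site_fixture(SiteConfig(seed=3, noise_sd=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
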