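import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from marshmem import (
    Scenario,
    default_site,
    hindcast_scenario,
)


@pytest.fixture(scope="session")
def site():
    """Default brackish-marsh parameterization used across the suite."""
    return default_site()


@pytest.fixture(scope="session")
def hindcast(site):
    """Constant 24 cm/century forcing at the site's current SSC."""
    return Scenario(hindcast_scenario(), "high", site.physical.ssc)
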