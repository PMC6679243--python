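import pytest
from hypothesis import HealthCheck, settings

import breathradar as br

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def config() -> br.RadarConfig:
    """Default radar link: effective RF 2.0 GHz, 100 Hz baseband."""
    return br.RadarConfig()


@pytest.fixture(scope="session")
def lam(config) -> float:
    return br.wavelength(config)


@pytest.fixture()
def optimum_channel(lam) -> br.PropagationChannel:
    """Channel at the first optimum detection point (d0 = lambda/8)."""
    return br.PropagationChannel(nominal_distance_m=lam / 8.0)
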