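import pytest
from hypothesis import HealthCheck, settings

import flowkick as fk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    return fk.ModelParams()


@pytest.fixture(scope="session")
def regime_vi():
    """Savanna-savanna bistable exemplar: two stable coexistence states."""
    return fk.DisturbanceRegime(0.25, 0.6, 2.0)


@pytest.fixture(scope="session")
def census_vi(regime_vi, params):
    return fk.enumerate_fixed_points(regime_vi, params)


@pytest.fixture(scope="session")
def regime_iii():
    """Mono-stable coexistence regime, far from every bifurcation locus."""
    return fk.DisturbanceRegime(0.15, 0.2, 2.0)
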