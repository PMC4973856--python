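import pytest
from hypothesis import HealthCheck, settings

from asdest import DesignConfig, StageSummaries, derive_quantities

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    # design fixtures are frozen dataclasses, safe to share across examples
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def ad_design():
    """The Alzheimer's-trial worked example: SIB-score outcome, sigma=13.2,
    200 patients per stage, prevalence 0.5, no margin or futility rule."""
    return DesignConfig(n1=200, n2=200, sigma=13.2, p_S=0.5, b=0.0)


@pytest.fixture
def ad_quantities(ad_design):
    return derive_quantities(ad_design, 100, 100)


@pytest.fixture
def scenario1():
    return StageSummaries(x=6.5, y=5.6, s_X=100, u=7.42)


@pytest.fixture
def scenario3():
    return StageSummaries(x=5.4, y=6.0, s_X=100, v=7.42, w=3.82, s_V=100)


@pytest.fixture
def scenario4():
    return StageSummaries(x=5.7, y=5.7, s_X=100, v=7.42, w=3.82, s_V=100)
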