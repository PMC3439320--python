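import pytest
from hypothesis import HealthCheck, settings

import ergocost as ec

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def profile() -> ec.CostProfile:
    return ec.reference_profile()


@pytest.fixture(scope="session")
def design() -> ec.DesignParameters:
    return ec.reference_design()


@pytest.fixture(scope="session")
def baseline(profile, design) -> ec.Baseline:
    return ec.Baseline(profile=profile, design=design)


@pytest.fixture(scope="session")
def scenarios() -> list[ec.Scenario]:
    return ec.reference_scenarios()


@pytest.fixture(scope="session")
def attribution() -> ec.StakeholderAttribution:
    return ec.reference_attribution()
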