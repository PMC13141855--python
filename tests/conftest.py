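import pytest
from hypothesis import settings, HealthCheck

from eadiff import build_feature_matrix, core_prevalence_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def core_cohort():
    return core_prevalence_fixture()


@pytest.fixture(scope="session")
def core_matrix(core_cohort):
    return build_feature_matrix(core_cohort)
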