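import pytest
from hypothesis import HealthCheck, settings

from neuroprog.synthetic import SyntheticSpec, generate_cohort, named_fixture

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table3_cohort():
    """Fixture cohort reproducing the +A/+H >=2-lobes contingency counts."""
    return named_fixture("table3_both")


@pytest.fixture(scope="session")
def synth_cohort():
    """A moderate synthetic cohort with the default generating model."""
    return generate_cohort(SyntheticSpec(n=400, seed=7))
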