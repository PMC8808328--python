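import pytest
from hypothesis import HealthCheck, settings

from larc_cea import ParameterSet, base_case_parameters

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def base() -> ParameterSet:
    return base_case_parameters()
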