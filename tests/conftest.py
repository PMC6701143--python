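import pytest
from hypothesis import HealthCheck, settings

from fermbalance import SubstrateSpec

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def substrate() -> SubstrateSpec:
    """Reference loading: 200 g/l raw starch as-is, 183.3 g/l dry, 5 g/l glucose."""
    return SubstrateSpec(starch_as_is=200.0, starch_dry=183.3, added_glucose=5.0)
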