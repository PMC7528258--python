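import pytest
from hypothesis import HealthCheck, settings

from surpval import BROWN_HDPS

# the shared estimate fixture is a frozen dataclass, safe to reuse across examples
settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def brown():
    """The worked-example hazard ratio: 1.61, 95% limits (0.997, 2.59)."""
    return BROWN_HDPS
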