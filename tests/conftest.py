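import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def carbon_grid():
    """A 40-60 ppm window at the standard 0.05 ppm spacing."""
    return np.arange(40.0, 60.0 + 1e-9, 0.05)
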