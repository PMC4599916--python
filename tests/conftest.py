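import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def circle_pixel_oracle(shape, center, radius):
    """Independent full-frame rasterization oracle: pixel centers inside the circle."""
    rr, cc = np.indices(shape)
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return set(zip(rr[inside].tolist(), cc[inside].tolist()))
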