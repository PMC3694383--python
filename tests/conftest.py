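import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def checkerboard():
    """8x8 0/1 checkerboard used by several hand-computed fixtures."""
    from mritex import GrayImage

    return GrayImage(np.indices((8, 8)).sum(axis=0) % 2, levels=2)
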