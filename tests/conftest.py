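import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_fp(*on_bits: int, length: int = 16) -> np.ndarray:
    """Binary fingerprint with the given bits set."""
    fp = np.zeros(length, dtype=np.uint8)
    if on_bits:
        fp[list(on_bits)] = 1
    return fp


@pytest.fixture
def fp_factory():
    return make_fp
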