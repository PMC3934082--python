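import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_unit_dictionary(rng, d, n):
    """Random dictionary with unit-norm columns and a unit test vector."""
    A = rng.standard_normal((d, n))
    A /= np.linalg.norm(A, axis=0)
    y = rng.standard_normal(d)
    y /= np.linalg.norm(y)
    return A, y
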