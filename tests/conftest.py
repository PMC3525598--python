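import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from inframe import builtin_primer_set

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def primer_set():
    return builtin_primer_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(20121218)


def within_3se(observed_frac: float, expected_frac: float, n: int) -> bool:
    """Binomial 3-standard-error acceptance band around the expectation."""
    se = np.sqrt(max(expected_frac * (1.0 - expected_frac), 1e-12) / n)
    return abs(observed_frac - expected_frac) <= 3.0 * se + 1e-12
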