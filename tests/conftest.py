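import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_refs(rng):
    """Twenty random 40-nt references."""
    return ["".join(rng.choice(list("ACGT"), 40)) for _ in range(20)]


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), length))
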