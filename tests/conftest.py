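import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from orfsieve import GenomeSpec, generate_genome

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_genome():
    """A 20 kb, 10-gene synthetic genome shared across tests."""
    return generate_genome(GenomeSpec(20_000, 10, (300, 900), 0.5, seed=7))


@pytest.fixture(scope="session")
def medium_genome():
    """The 100 kb, 50-gene genome used for chance-level frame statistics."""
    return generate_genome(GenomeSpec(100_000, 50, (300, 3000), 0.5, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
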