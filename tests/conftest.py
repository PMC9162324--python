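import numpy as np
import pytest
from hypothesis import settings

from balsel.counts import PolymorphismCounts

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_tables(rng):
    """1,000 random small count tables with all cells positive."""
    cells = rng.integers(1, 60, size=(1000, 4))
    return [PolymorphismCounts(*row) for row in cells]
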