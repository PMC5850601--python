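import numpy as np
import pytest

from erselect import SimDesign


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def standard_design():
    """Six replicates, Ne=300, 60 generations sampled every 10, 80x."""
    return SimDesign()


@pytest.fixture
def small_design():
    """Cheap design for smoke tests."""
    return SimDesign(ne=100, replicates=2, generations=30, interval=10, mean_coverage=40.0)
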