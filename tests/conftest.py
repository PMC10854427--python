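import numpy as np
import pytest

from ethoarena import synth


@pytest.fixture
def arena_config():
    return synth.ArenaConfig(seed=42)


@pytest.fixture
def small_config():
    """Small arena with a coarse 8-mic array for fast audio tests."""
    return synth.ArenaConfig(length_m=6.0, width_m=4.0, height_m=3.0,
                             n_mics=8, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
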