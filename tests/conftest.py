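import numpy as np
import pytest

from csfrtd.dataset import make_sequence_bank
from csfrtd.network import NetworkConfig
from csfrtd.synthetic_scene import BloomSimConfig, default_endmembers, simulate_series


@pytest.fixture(scope="session")
def endmembers():
    return default_endmembers()


@pytest.fixture(scope="session")
def compact_series(endmembers):
    """64x64, T=4 compact-bloom series used across modules."""
    cfg = BloomSimConfig(height=64, width=64, n_frames=4, morphology="compact",
                         n_blooms=1, seed=7)
    return simulate_series(endmembers, cfg)


@pytest.fixture
def tiny_net_config():
    """Smallest width set whose ASPC proportions stay integral."""
    return NetworkConfig(seq_len=2, stage_widths=(4, 8, 16, 32),
                         convlstm_hidden=4, seed=3)


@pytest.fixture(scope="session")
def tiny_split():
    """A small sequence bank shared by training-related tests."""
    return make_sequence_bank(n_train=10, n_test=4, seed=11, seq_len=2)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
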