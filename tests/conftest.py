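import numpy as np
import pytest

from ecgdelin.nn import NetConfig
from ecgdelin.synthetic import generate_population


@pytest.fixture(scope="session")
def beat_population():
    """Small shared population of jittered synthetic beats."""
    return generate_population(40, seed=123)


@pytest.fixture(scope="session")
def raw_beats(beat_population):
    return np.stack([b.samples for b in beat_population])


@pytest.fixture()
def tiny_config():
    """Smallest architecture that still exercises every stage
    (64 -> 32 -> 16 -> 8 -> 4; the pyramid pools 4 -> 2 -> 1)."""
    return NetConfig(input_len=64, stem_channels=8, growth=4,
                     block_layers=(2, 2, 2), bottleneck_mult=2,
                     cbam_reduction=2, final_channels=8, branch_dim=8,
                     hidden_dim=8, head="regression")
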