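import numpy as np
import pytest

from octaseg import ModelConfig, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_model_cfg():
    """Smallest config that still exercises every architectural piece."""
    from octaseg import DwamConfig

    return ModelConfig(
        trunk_channels=8, num_stages=1, expansion_width=12,
        dwam=DwamConfig(channels=8, fc_hidden=16, spatial_mid_channels=8),
        eag_mid_channels=4, seed=7,
    )


@pytest.fixture
def small_synth_cfg():
    """Generator config scaled to small rasters for fast tests."""
    return SyntheticConfig(size=(32, 32), width_root=3.0, n_trees=2, seed=5)
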