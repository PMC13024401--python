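import numpy as np
import pytest

from ecgrhythm import NoiseConfig, SynthDatasetConfig
from ecgrhythm.net import ModelConfig, RhythmTransformer


@pytest.fixture(scope="session")
def clean_cfg():
    """Noise-free generator configuration used by the peak/rate oracles."""
    return SynthDatasetConfig(per_class_count=6, seed=123, noise=NoiseConfig.clean())


@pytest.fixture(scope="session")
def noisy_cfg():
    return SynthDatasetConfig(per_class_count=6, seed=123, noise=NoiseConfig())


@pytest.fixture(scope="session")
def tiny_model():
    """A small float64 model for exact numeric checks."""
    cfg = ModelConfig(
        d_model=6, n_layers=2, n_heads=2, key_dim=3, ffn_dim=8, dropout=0.0,
        t2v_k=2, window_len=10, head_hidden=4, dtype="float64",
    )
    return RhythmTransformer(cfg, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
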