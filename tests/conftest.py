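import numpy as np
import pytest

from uesdist.datasets import SwallowSample
from uesdist.model import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Scaled-down architecture for fast mechanics tests; derived sizes
    follow the same rules as the full model."""
    return ModelConfig(chunk_len=16, channels_in=3, conv1_filters_per_channel=2,
                       kernel_len=3, T=8, gru_layers=2, gru_units=6,
                       attn_hidden=12, fc_units=8, fc_layers=3,
                       dropout_rate=0.2, epochs=5, batch_size=4,
                       learning_rate=3e-3)


def make_planted_samples(config, n, seed, noise=0.05):
    """Cheap model-input fixtures: within-mask chunk amplitude encodes the
    target ratio (0.1 + 0.9*ratio), mimicking the simulator's planted
    monotone energy-ratio mapping without running the full front end."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        ratio = float(rng.uniform(0.2, 0.8))
        onset = int(rng.integers(1, config.T // 2))
        offset = int(rng.integers(onset, config.T - 1))
        mask = np.zeros(config.T, dtype=np.float32)
        mask[onset : offset + 1] = 1.0
        chunks = noise * rng.standard_normal(
            (config.T, config.chunk_len, config.channels_in))
        amp = 0.1 + 0.9 * ratio
        chunks[onset : offset + 1] += amp * rng.standard_normal(
            (offset - onset + 1, config.chunk_len, config.channels_in))
        samples.append(SwallowSample(chunks=chunks.astype(np.float32), mask=mask,
                                     target_ratio=ratio, valid_chunks=config.T,
                                     swallow_id=f"p{i:03d}"))
    return samples


@pytest.fixture
def planted_samples(tiny_config):
    return make_planted_samples(tiny_config, 32, seed=5)
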