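import numpy as np
import pytest

from ecogflex import MorletParams, ModelConfig, SynthConfig, generate_recording


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale generator conditions for unit tests: 8 channels, 24 s."""
    return SynthConfig(n_channels=8, duration=24.0, channels_per_finger=1, seed=3)


@pytest.fixture(scope="session")
def small_recording(small_cfg):
    return generate_recording(small_cfg)


@pytest.fixture(scope="session")
def small_morlet():
    """A light filter bank for spectrogram unit tests."""
    return MorletParams(n_freqs=12)


@pytest.fixture()
def tiny_model_cfg():
    """A few-thousand-parameter config; forward/backward in milliseconds."""
    return ModelConfig(
        in_features=24,
        layer_dims=(8, 8, 12, 12, 16, 16),
        kernel_sizes=(3, 3, 3, 3, 3),
        dilations=(1, 2, 3, 1, 2),
        dropout=0.1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
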