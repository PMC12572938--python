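import numpy as np
import pytest

from spikewav import LIFConfig, ModelConfig, SynthSpec, build_model, make_montage


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture(scope="session")
def montage32():
    return make_montage(32)


@pytest.fixture(scope="session")
def montage8():
    return make_montage(8)


@pytest.fixture
def tiny_model_cfg():
    """A model small enough for sub-second forward passes in unit tests."""
    return ModelConfig(
        t_steps=2, n_blocks=1, d=8, patch_grid=4, heads=2, mlp_ratio=2,
        grid=16, lif=LIFConfig(), seed=1,
    )


@pytest.fixture
def tiny_model(tiny_model_cfg):
    return build_model(tiny_model_cfg)


@pytest.fixture(scope="session")
def small_spec():
    """Fast synthetic dataset: 8 channels, short trials, few per class."""
    return SynthSpec(n_channels=8, trial_length_s=2.0, n_trials_per_class=4, seed=7)
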