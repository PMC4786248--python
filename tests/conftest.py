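import numpy as np
import pytest

from pleurascan import PhantomConfig, make_bmode_phantom, make_mmode_phantom


@pytest.fixture
def sliding_config():
    """Negative exam: 4-px sinusoidal sliding over a 10-frame period."""
    return PhantomConfig(
        sliding_amplitude_px=4.0, sliding_period_frames=10, n_frames=20, seed=7
    )


@pytest.fixture
def positive_config():
    """Pneumothorax exam: no sliding, no B-lines."""
    return PhantomConfig(
        truth_label="positive", sliding_amplitude_px=0.0, n_blines=0, seed=3
    )


@pytest.fixture
def bline_config():
    """Negative exam whose only sign is two static B-lines."""
    return PhantomConfig(sliding_amplitude_px=0.0, n_blines=2, seed=5)


@pytest.fixture
def seashore_config():
    return PhantomConfig(
        mmode_pattern="seashore", truth_label="negative",
        sliding_amplitude_px=4.0, seed=11,
    )


@pytest.fixture
def stratosphere_config():
    return PhantomConfig(
        mmode_pattern="stratosphere", truth_label="positive",
        sliding_amplitude_px=0.0, n_blines=0, pleural_depth_px=70, seed=11,
    )


@pytest.fixture
def sliding_clip(sliding_config):
    return make_bmode_phantom(sliding_config).payload


@pytest.fixture
def positive_clip(positive_config):
    return make_bmode_phantom(positive_config).payload


@pytest.fixture
def seashore_image(seashore_config):
    return make_mmode_phantom(seashore_config).payload


@pytest.fixture
def stratosphere_image(stratosphere_config):
    return make_mmode_phantom(stratosphere_config).payload
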