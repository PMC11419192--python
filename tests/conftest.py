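import numpy as np
import pytest

from cherenseg import phantom
from cherenseg.segnet import NetworkConfig, build_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_source_spec():
    return phantom.source_spec(shape=(128, 128), width_range=(3.0, 6.0),
                               depth=4, branch_prob=0.6, n_steps=14, step=6.0)


@pytest.fixture
def small_target_spec():
    return phantom.target_spec(shape=(128, 128), width_range=(3.0, 6.0),
                               depth=4, branch_prob=0.6, n_steps=14, step=6.0)


@pytest.fixture
def tiny_net():
    """Smallest usable backbone for fast structural tests."""
    return build_model(NetworkConfig(init_filters=4, levels=2,
                                     blocks_per_level=(1, 1)), seed=0)
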