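import numpy as np
import pytest

from camformer.zoo import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def micro_config():
    """A few-thousand-parameter architecture for fast training tests."""
    return ModelConfig(conv_channels=[8, 8], kernel_sizes=[5, 5],
                       residual_after=[2], penultimate_maxpool=True,
                       pool_width=11, fc_dims=[8], dropout=[0.0],
                       batchnorm=True, input_channels=4)


def random_promoter(rng, length=110):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))
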