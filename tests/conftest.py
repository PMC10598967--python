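import numpy as np
import pytest

from m6amstack import synthetic_data as sd
from m6amstack.base_models import BaseModelSpec, TrainConfig

# small hyperparameter variants used by training smoke tests so the
# non-acceptance suite stays fast; structure-inspection tests use defaults
TINY_HP = {
    "densenet_senet": dict(growth=8, layers_per_block=2, head_units=16),
    "dcnn_bilstm": dict(filters=8, lstm_units=8),
    "msrn_bigru": dict(block_channels=16, fusion_filters=32, gru_units=8),
}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec_factory():
    def make(architecture, input_shape=(41, 4)):
        return BaseModelSpec(architecture, hyperparameters=TINY_HP[architecture],
                             input_shape=input_shape)
    return make


@pytest.fixture
def fast_config():
    return TrainConfig(epochs=5, batch_size=64, seed=0,
                       early_stopping_patience=5)


@pytest.fixture(scope="session")
def strong_dataset():
    """Strongly separable windows (effect=1 planted motif)."""
    return sd.generate_dataset(150, 150, delta=20,
                               motif=sd.default_motif(1.0), seed=42)


@pytest.fixture(scope="session")
def null_dataset():
    return sd.generate_dataset(150, 150, delta=20,
                               motif=sd.default_motif(0.0), seed=43)
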