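import numpy as np
import pytest

from echotherm.datasets import simulate_feature_dataset
from echotherm.model import TrainConfig
from echotherm.network import ModelConfig
from echotherm.synthetic import HeatingModel, TextureModel
from echotherm.train import split_experiments, train


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# small-but-realistic conditions for unit-level fixtures: a 150 s heating run
# imaged at 10 fps on a 16 px patch keeps every code path exercised while the
# full-scale defaults are reserved for the end-to-end acceptance checks
SHORT_HEATING = HeatingModel(duration=150.0)
SMALL_TEXTURE = TextureModel(roi_size=16, frame_rate=10.0)


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate_feature_dataset(
        4, heating=SHORT_HEATING, tex=SMALL_TEXTURE, seed=7
    )


@pytest.fixture(scope="session")
def tiny_split(tiny_dataset):
    return split_experiments(tiny_dataset.features, 0.7, seed=0)


@pytest.fixture(scope="session")
def tiny_results(tiny_split):
    train_set, _ = tiny_split
    cfg = ModelConfig()
    tc = TrainConfig(epochs=3, seed=0, train_stride=24)
    return train(cfg, tc, train_set)
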