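import numpy as np
import pytest

from succsite import GeneratorSpec, RunConfig, TrainedModel, generate

PLANTED = (-2, 1)


@pytest.fixture(scope="session")
def train_fragments():
    """Small labeled 1:10 dataset with signal planted at offsets -2 and +1."""
    return generate(
        GeneratorSpec(n_pos=200, n_neg=2000, planted_offsets=PLANTED,
                      effect_size=0.5, seed=11)
    )


@pytest.fixture(scope="session")
def test_fragments():
    return generate(
        GeneratorSpec(n_pos=120, n_neg=1200, planted_offsets=PLANTED,
                      effect_size=0.5, seed=97)
    )


@pytest.fixture(scope="session")
def trained_model(train_fragments):
    return TrainedModel.fit(train_fragments, RunConfig())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
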