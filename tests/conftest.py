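import numpy as np
import pytest

from ttafoods import (
    DOMAINS,
    build_default_augmentations,
    extract_layer_features,
    fit_foods,
    generate_dataset,
    make_toy_adapter,
)


@pytest.fixture(scope="session")
def identity_train():
    return generate_dataset(12, DOMAINS["identity"], image_size=64, seed=1)


@pytest.fixture(scope="session")
def toy_adapter(identity_train):
    return make_toy_adapter(identity_train)


@pytest.fixture(scope="session")
def train_features(toy_adapter, identity_train):
    return extract_layer_features(toy_adapter, identity_train.images)


@pytest.fixture(scope="session")
def foods_model(train_features):
    return fit_foods(train_features)


@pytest.fixture(scope="session")
def default_augset():
    return build_default_augmentations(64)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_image(rng):
    return rng.random((64, 64, 3))
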