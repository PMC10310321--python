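import numpy as np
import pytest

from vvsreadout import (
    RandomConvEncoder,
    extract_features,
    flatten_pixels,
    generate_morph_stimuli,
    generate_oddity_pool,
)
from vvsreadout.encoders import extract_feature_layers


@pytest.fixture(scope="session")
def encoder():
    return RandomConvEncoder(seed=0)


@pytest.fixture(scope="session")
def morph_small():
    """Cheap morph set for unit tests: 4 sequences x 7 levels at 48 px."""
    return generate_morph_stimuli(n_sequences=4, n_levels=7, image_size=48, colinearity=0.9, seed=11)


@pytest.fixture(scope="session")
def morph_full():
    """The study-scale morph set: 7 sequences x 11 levels (levels 0..100)."""
    return generate_morph_stimuli(n_sequences=7, n_levels=11, image_size=64, colinearity=0.9, seed=1)


@pytest.fixture(scope="session")
def fc6_full(encoder, morph_full):
    return extract_features(encoder, morph_full, "fc6")


@pytest.fixture(scope="session")
def pixels_full(morph_full):
    return flatten_pixels(morph_full)


@pytest.fixture(scope="session")
def oddity_pool_small():
    return generate_oddity_pool(n_objects=6, n_views=8, image_size=48, seed=7)


@pytest.fixture(scope="session")
def characterization_layers(encoder):
    """All-layer features of a shape-on-noise pool, used for encoding-model fits."""
    pool = generate_oddity_pool(n_objects=24, n_views=8, image_size=64, seed=9)
    return extract_feature_layers(encoder, pool, list(encoder.layers))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
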