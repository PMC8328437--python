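import numpy as np
import pytest

from morphsvm.config import PipelineConfig
from morphsvm.fixtures import FixtureSpec, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pattern_dataset():
    """Noiseless separable 5-class oriented-pattern set, 128x128."""
    return make_dataset(FixtureSpec(
        regime="pattern", n_classes=5, n_per_class=10,
        image_size=(128, 128), separation=1.0, noise_sd=0.0, seed=7,
    ))


@pytest.fixture(scope="session")
def texture_dataset():
    """Noiseless separable 3-class micro-texture set, 128x128."""
    return make_dataset(FixtureSpec(
        regime="texture", n_classes=3, n_per_class=10,
        image_size=(128, 128), separation=1.0, noise_sd=0.0, seed=11,
    ))


@pytest.fixture(scope="session")
def hog_small_fn():
    """HOG feature function sized for 128x128 test images."""
    fn, _ = PipelineConfig(descriptor="hog", hog_cell=32).feature_extractor()
    return fn


@pytest.fixture(scope="session")
def hog_lbp_small_fn():
    """HOG+LBP feature function sized for 128x128 test images."""
    fn, _ = PipelineConfig(
        descriptor="hog+lbp", hog_cell=32, lbp_cell=32
    ).feature_extractor()
    return fn
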