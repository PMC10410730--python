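import numpy as np
import pytest

from dendrimod import synthetic_data as sd


@pytest.fixture(scope="session")
def dataset_2d():
    return sd.gen_2d_multitask(n_tasks=8, n_samples=256, seed=11)


@pytest.fixture(scope="session")
def glyph_set():
    images, labels = sd.gen_glyph_images(
        n_classes=4, image_size=16, n_per_class=20, seed=7)
    return images, labels


@pytest.fixture(scope="session")
def glyph_dataset(glyph_set):
    images, labels = glyph_set
    return sd.to_one_vs_all(images, labels, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
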