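import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")

from pixelseg import (
    Image,
    LabelMap,
    PhantomSpec,
    make_texture_phantom,
    normalize_intensity,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_texture_pair():
    """A 48x48 3-class textured phantom, normalized, with its label map."""
    img, lm = make_texture_phantom(
        PhantomSpec(kind="texture2d", size=(48, 48), classes=3, seed=7)
    )
    return normalize_intensity(img), lm


@pytest.fixture
def halves_pair():
    """A two-class image split by a single straight vertical boundary."""
    img, lm = make_texture_phantom(
        PhantomSpec(
            kind="texture2d",
            size=(32, 32),
            classes=2,
            seed=3,
            layout="halves",
            noise_sigma=0.0,
            texture_amps=(0.0, 0.0),
        )
    )
    return normalize_intensity(img), lm


@pytest.fixture
def random_image(rng):
    return Image(data=rng.uniform(0, 255, size=(20, 24, 1)))


@pytest.fixture
def random_labelmap(rng):
    return LabelMap(labels=rng.integers(0, 3, size=(20, 24)))
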