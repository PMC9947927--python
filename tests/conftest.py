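import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles helper module

from subloc2l.fixtures import SyntheticSpec, generate_dataset
from subloc2l.imaging import separate_stains
from subloc2l.features.api import extract_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231001)


@pytest.fixture(scope="session")
def small_image(rng):
    """A 32x32 textured grayscale image (spots + gradient + noise)."""
    yy, xx = np.mgrid[0:32, 0:32]
    img = 40 + 3.0 * xx + 25 * np.sin(yy / 2.0) + rng.normal(0, 8, (32, 32))
    img[10:14, 5:9] += 90
    img[22:25, 20:26] += 70
    return np.clip(img, 0, 255)


@pytest.fixture(scope="session")
def tiny_corpus():
    """A small synthetic image corpus shared across image-level tests."""
    spec = SyntheticSpec(images_per_class=3, image_size=(64, 64), seed=7)
    images, labels, manifest = generate_dataset(spec)
    return spec, images, labels, manifest


@pytest.fixture(scope="session")
def tiny_feature_sets(tiny_corpus):
    spec, images, labels, _ = tiny_corpus
    pairs = [
        separate_stains(img, spec.stain_basis, source_id=f"img{i}")
        for i, img in enumerate(images)
    ]
    return extract_dataset(pairs, labels)
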