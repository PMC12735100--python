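import numpy as np
import pytest

from macnext.config import MACNeXtConfig, TINY_PRESET
from macnext.synthetic import (
    TABLE1_CLASSES,
    DatasetManifest,
    default_class_specs,
    render_arrays,
)
from macnext.training import ArrayDataset


def tiny_config(**overrides) -> MACNeXtConfig:
    """Small valid architecture for fast tests."""
    kw = dict(TINY_PRESET)
    kw.update(overrides)
    return MACNeXtConfig(**kw)


@pytest.fixture(scope="session")
def specs():
    return default_class_specs()


@pytest.fixture(scope="session")
def four_class_dataset(specs):
    """The learnability benchmark dataset: 4 classes x 200 images at 64x64."""
    manifest = DatasetManifest(
        [(cid, name, 200) for cid, name, _ in TABLE1_CLASSES[:4]], seed=11
    )
    images, labels, names = render_arrays(manifest, specs, image_size=64)
    return ArrayDataset(images, labels, names)


@pytest.fixture(scope="session")
def small_dataset(specs):
    """A smaller 4-class set (40/class at 48x48) for quick training checks."""
    manifest = DatasetManifest(
        [(cid, name, 40) for cid, name, _ in TABLE1_CLASSES[:4]], seed=7
    )
    images, labels, names = render_arrays(manifest, specs, image_size=48)
    return ArrayDataset(images, labels, names)
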