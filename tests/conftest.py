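import numpy as np
import pytest

from mrfopt.encoding import default_space
from mrfopt.fitness import SplitData
from mrfopt.fixtures import SyntheticDatasetSpec, generate_image_dataset
from mrfopt.preprocessing import split_dataset


@pytest.fixture(scope="session")
def space():
    return default_space()


@pytest.fixture(scope="session")
def binary_dataset():
    """Small separable 2-class synthetic image set (32px, moderate noise)."""
    spec = SyntheticDatasetSpec(
        n_classes=2, n_per_class=30, image_size=32, noise_sd=10.0, seed=1
    )
    return generate_image_dataset(spec)


@pytest.fixture(scope="session")
def binary_splits(binary_dataset):
    images, labels = binary_dataset
    sp = split_dataset(len(labels), labels, ratio=0.85, seed=0)
    return SplitData(
        train_x=images[sp.train_ids],
        train_y=labels[sp.train_ids],
        val_x=images[sp.validation_ids],
        val_y=labels[sp.validation_ids],
        test_x=images[sp.test_ids],
        test_y=labels[sp.test_ids],
    )
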