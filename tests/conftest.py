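"""Shared fixtures: one session-scoped trained classifier and its dataset.

The model is trained once on synthetic crops whose side matches the
pipeline's extraction size, so plate-level tests exercise the same resize
path the production flow uses.
"""

from __future__ import annotations

import numpy as np
import pytest

from sitia.classifier import (
    Cnn6,
    SplitSpec,
    TrainingConfig,
    split_balanced,
    train_from_scratch,
)
from sitia.synthetic import make_crop_dataset

# crop side matched to a 24 px fly at the generator's fill ratio
TRAIN_CROP_PX = 56
TRAIN_SEED = 3


@pytest.fixture(scope="session")
def crop_dataset():
    return make_crop_dataset(300, TRAIN_CROP_PX, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def dataset_split(crop_dataset):
    return split_balanced(crop_dataset, SplitSpec(seed=TRAIN_SEED))


@pytest.fixture(scope="session")
def trained_model(dataset_split):
    model = Cnn6(seed=TRAIN_SEED)
    model, _curves = train_from_scratch(
        model, dataset_split, TrainingConfig(epochs=25, seed=TRAIN_SEED)
    )
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
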