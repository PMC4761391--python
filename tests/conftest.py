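"""Shared fixtures: the default synthetic study set and its feature table."""

import numpy as np
import pytest

from memopred.features import extract_feature_table
from memopred.synthetic_data import generate_dataset


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default synthetic study set: 200 sequences per class, seed 7."""
    return generate_dataset(200, seed=7)


@pytest.fixture(scope="session")
def synthetic_table(synthetic_dataset):
    """Feature table (id, label, 80 features) of the default synthetic set."""
    return extract_feature_table(synthetic_dataset)


@pytest.fixture(scope="session")
def synthetic_Xy(synthetic_table):
    X = synthetic_table.drop(columns=["id", "label"]).to_numpy(dtype=float)
    y = synthetic_table["label"].astype(str).to_numpy()
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
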