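"""Shared fixtures: synthetic crop datasets and a trained classifier bundle."""

import numpy as np
import pytest

import flytrap as ft


@pytest.fixture(scope="session")
def crop_dataset() -> ft.LabelledDataset:
    """500 olive flies + 500 others (default generator separation)."""
    crops, labels = ft.generate_crop_dataset(500, 250, 250, seed=42)
    return ft.LabelledDataset(crops=crops, labels3=labels)


@pytest.fixture(scope="session")
def split(crop_dataset):
    return ft.split_dataset(crop_dataset, val_fraction=0.1, seed=0)


@pytest.fixture(scope="session")
def bundle(split) -> ft.ClassifierBundle:
    """RF + SVM trained with the deployed hyperparameters."""
    train_ds, _ = split
    return ft.train_bundle(train_ds)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
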