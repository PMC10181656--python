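"""Shared fixtures: a small synthetic dataset and a trained tiny CNN.

Session-scoped so the (cheap but not free) training cost is paid once.
"""

import numpy as np
import pytest

import camconcord as cx


@pytest.fixture(scope="session")
def small_cfg() -> cx.SyntheticConfig:
    return cx.SyntheticConfig(n_images=60, image_size=32, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return cx.generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def trained_model(small_dataset, small_cfg):
    adapter = cx.build_tiny_cnn(small_cfg.image_size, small_cfg.channels, seed=11)
    adapter, _ = cx.train(
        adapter, small_dataset, cx.TrainConfig(epochs=6, seed=11)
    )
    return adapter


@pytest.fixture(scope="session")
def test_images(small_dataset):
    return [s for s in small_dataset if s.split == "test"]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
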