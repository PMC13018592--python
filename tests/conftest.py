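"""Shared fixtures: a small phantom dataset and a network trained on it.

The fixture network is a scaled-down variant (three residual blocks of
8/16/32 channels on 48-px phantoms) of the full five-block architecture —
the adaptive pooling head makes the architecture size-agnostic, so the same
code paths are exercised at a fraction of the cost.
"""

import numpy as np
import pytest

import trustnet as tn

TEST_IMAGE_SIZE = 48
TEST_BLOCKS = (8, 16, 32)


def small_config(**overrides) -> tn.NetworkConfig:
    defaults = dict(block_channels=TEST_BLOCKS, latent_dim=16, pool_output=2)
    defaults.update(overrides)
    return tn.NetworkConfig(**defaults)


def small_training(**overrides) -> tn.TrainingConfig:
    defaults = dict(epochs=60, batch_size=16, learning_rate=3e-3, seed=0, patience=15)
    defaults.update(overrides)
    return tn.TrainingConfig(**defaults)


def labels_of(images) -> np.ndarray:
    return np.array([tn.LABELS.index(img.label) for img in images])


@pytest.fixture(scope="session")
def easy_dataset() -> tn.PhantomDataset:
    """200 high-contrast phantoms: a model can learn these to ~100%."""
    return tn.generate_dataset(n=200, seed=1, image_size=TEST_IMAGE_SIZE,
                               difficulty_mix=tn.EASY_ONLY_MIX)


@pytest.fixture(scope="session")
def mixed_dataset() -> tn.PhantomDataset:
    """Mixed-difficulty phantoms (60% easy / 40% near the noise floor).

    The validation split is deliberately large (~100 images): the MSI
    threshold D is a sample maximum and needs dozens of TP/TN cases to
    stabilize.
    """
    return tn.generate_dataset(n=240, seed=7, image_size=TEST_IMAGE_SIZE,
                               split_fractions=(0.25, 0.45, 0.30))


@pytest.fixture(scope="session")
def trained_net(easy_dataset) -> tn.TrustNet:
    net = tn.build_network(small_config(), seed=0)
    net, history = tn.train_network(
        net, easy_dataset.split("train"), easy_dataset.split("validation"),
        small_training(),
    )
    assert history.val_acc.max() >= 0.9, "fixture model failed to learn"
    return net
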