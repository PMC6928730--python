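import numpy as np
import pytest

from cavity2vec import TrainConfig, generate_trajectories, train
from cavity2vec.synthetic import generate_molecule


@pytest.fixture(scope="session")
def clean_dataset():
    """Three templates, zero noise: sequences within a template are identical."""
    return generate_trajectories(
        k_templates=3, n_per_template=10, node_dropout_prob=0.0,
        node_swap_prob=0.0, seed=7, n_atoms=250, length_range=(8, 16),
    )


@pytest.fixture(scope="session")
def noisy_dataset():
    """Three templates with per-node dropout and swap noise."""
    return generate_trajectories(
        k_templates=3, n_per_template=20, node_dropout_prob=0.1,
        node_swap_prob=0.05, seed=11, n_atoms=250, length_range=(8, 16),
    )


@pytest.fixture(scope="session")
def clean_model(clean_dataset):
    """Small skip-gram model trained on the zero-noise corpus."""
    return train(
        clean_dataset.corpus(),
        TrainConfig(dimension=16, window=2, negative=5, epochs=25, seed=3),
    )


@pytest.fixture
def random_atoms():
    return generate_molecule(100, box=(30, 30, 30), seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
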