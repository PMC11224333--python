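import numpy as np
import pytest

from chimpfs.feature_selection import FitnessConfig, split_dataset
from chimpfs.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny8_split():
    """D=8 synthetic dataset with a fixed 70/30 split (oracle-enumerable)."""
    spec = SyntheticSpec(n_samples=60, n_classes=2, n_informative=2,
                         n_redundant=2, n_noise=4, class_separation=3.0,
                         seed=42)
    dataset, truth = generate_dataset(spec)
    split = split_dataset(dataset, 0.7, np.random.default_rng(0))
    return split, truth


@pytest.fixture(scope="session")
def small_split():
    """n=60, D=50 dataset with a fixed split, for optimizer-level tests."""
    spec = SyntheticSpec(n_samples=60, n_classes=2, n_informative=5,
                         n_redundant=5, n_noise=40, class_separation=2.0,
                         seed=7)
    dataset, truth = generate_dataset(spec)
    split = split_dataset(dataset, 0.7, np.random.default_rng(1))
    return split, truth


@pytest.fixture
def fitness_config():
    return FitnessConfig()
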