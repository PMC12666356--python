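import numpy as np
import pytest

from rfgr import SegmentDataset, SynthConfig, generate_balanced_dataset
from rfgr.features import RFGRConfig


@pytest.fixture(scope="session")
def small_dataset() -> SegmentDataset:
    """3 recordings per class -> 345 segments; shared read-only fixture."""
    return generate_balanced_dataset(3, SynthConfig(master_seed=7))


@pytest.fixture(scope="session")
def tiny_config() -> RFGRConfig:
    """Scaled-down fusion config for fast unit tests."""
    return RFGRConfig(
        n_trees=10, recurrent_units=8, epochs=2, cross_fit_folds=3, seed=11
    )


@pytest.fixture
def toy_features():
    """Well-separated 3-class tabular toy (60 rows, 4 features)."""
    rng = np.random.default_rng(5)
    centers = np.array([[0, 0, 0, 0], [6, 6, 0, 0], [0, 6, 6, 6]], dtype=float)
    X = np.concatenate([c + rng.normal(scale=0.3, size=(20, 4)) for c in centers])
    y = np.repeat([1, 2, 3], 20)
    return X, y
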