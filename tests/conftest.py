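import numpy as np
import pytest

from tabdeg import SimulationConfig, simulate_counts
from tabdeg.config import TabNetConfig
from tabdeg.tabnet import TabNetClassifier


@pytest.fixture(scope="session")
def small_dataset():
    """400 genes, 20+20 samples, planted DEGs at |log2FC| = 2."""
    return simulate_counts(SimulationConfig(n_genes=400, seed=42))


@pytest.fixture(scope="session")
def separable_toy():
    """Linearly separable 3-class problem: 300 rows x 10 features, one
    constant column appended (11 features total)."""
    rng = np.random.default_rng(0)
    centers = rng.normal(size=(3, 10)) * 3
    X = np.vstack([centers[i] + rng.normal(size=(100, 10)) for i in range(3)])
    X = np.hstack([X, np.full((300, 1), 3.7)])  # constant feature
    y = np.repeat([0, 1, 2], 100)
    return X, y


@pytest.fixture(scope="session")
def trained_toy(separable_toy):
    X, y = separable_toy
    clf = TabNetClassifier(TabNetConfig(), seed=0)
    clf.fit(X, y)
    return clf, X, y
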