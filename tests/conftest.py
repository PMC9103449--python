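import numpy as np
import pytest

import nrsurrogate as nr


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark draw (n=86, seed 0)."""
    return nr.generate_dataset(seed=0)


@pytest.fixture(scope="session")
def augmented(benchmark):
    """Benchmark after the NNI stage (86 -> 1806 rows)."""
    return nr.nni_augment(benchmark, seed=0)


@pytest.fixture(scope="session")
def balanced(augmented):
    """Benchmark after NNI + K-means/SMOTE balancing."""
    assignment = nr.cluster(augmented, K=2, seed=0)
    return nr.smote_augment(augmented, assignment, seed=0)


@pytest.fixture(scope="session")
def fitted_gbt(balanced):
    """Default boosted-tree surrogate on the balanced benchmark."""
    return nr.fit_gbt(balanced, seed=0)


@pytest.fixture()
def tiny_table():
    """Hand-sized table with a known linear target."""
    rng = np.random.default_rng(7)
    X = rng.uniform(0, 1, size=(40, 3))
    y = 1.0 + 2.0 * X[:, 0] - 1.0 * X[:, 1] + 0.5 * X[:, 2]
    return nr.FeatureTable(X=X, y=y)
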