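import numpy as np
import pytest

from incfrnn.pool import TrainingPool, pool_insert


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def build_pool(X, labels) -> TrainingPool:
    """Pool from a feature matrix and label list, in row order."""
    X = np.asarray(X, dtype=float)
    pool = TrainingPool(X.shape[1])
    for x, lab in zip(X, labels):
        pool_insert(pool, x, lab)
    return pool


def random_pool(rng, n, d, n_classes=2):
    X = rng.uniform(0.0, 1.0, size=(n, d))
    labels = [f"c{rng.integers(n_classes)}" for _ in range(n)]
    return build_pool(X, labels), X, labels
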