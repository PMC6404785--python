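import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from esknn.knn_core import Dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_blobs(n_per_class: int, d: int, seed: int = 0, sep: float = 8.0) -> Dataset:
    """Two well-separated Gaussian clusters, labels 0/1."""
    g = np.random.default_rng(seed)
    X0 = g.normal(0.0, 1.0, size=(n_per_class, d))
    X1 = g.normal(sep, 1.0, size=(n_per_class, d))
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n_per_class, dtype=int), np.ones(n_per_class, dtype=int)])
    return Dataset(X, y)


def make_random_dataset(n: int, d: int, seed: int = 0) -> Dataset:
    """Unstructured continuous features with random balanced-ish labels;
    distance ties have probability zero."""
    g = np.random.default_rng(seed)
    X = g.normal(size=(n, d))
    y = g.integers(0, 2, size=n)
    if y.min() == y.max():  # ensure both classes present
        y[0] = 1 - y[0]
    return Dataset(X, y)


@pytest.fixture
def separable():
    return make_blobs(30, 3, seed=7)


def brute_knn_prob(X, y, queries, k):
    """Independent kNN oracle: full per-pair distance loop, sort by
    (distance, training index), count class-1 labels among the first k."""
    import math

    out = []
    for q in np.atleast_2d(queries):
        ranked = sorted((math.dist(q, x), i) for i, x in enumerate(X))
        out.append(sum(y[i] for _, i in ranked[:k]) / k)
    return np.array(out)
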