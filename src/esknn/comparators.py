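"""kNN-family baselines: plain kNN, bagged kNN (BkNN), random kNN
(RkNN) and the multiple-feature-subsets ensemble (MFS), plus thin
adapters to external random-forest and SVM implementations.

RkNN draws each member's feature subset WITHOUT replacement and trains
on all rows; MFS draws subsets WITH replacement (a feature may appear
twice, doubling its weight in the distance); BkNN bootstraps rows and
keeps all features.  All ensembles combine by majority vote over an odd
number of members.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .ensemble import draw_feature_subset
from .knn_core import (Dataset, _knn_prob, _neighbor_order, as_rng,
                       classify_from_probability, select_k_cv)

logger = logging.getLogger(__name__)

__all__ = [
    "ComparatorConfig",
    "knn_predict",
    "bagged_knn_predict",
    "random_knn_predict",
    "mfs_knn_predict",
    "external_comparator_predict",
]

_METHODS = ("knn", "bknn", "rknn", "mfs", "rf", "svm")


@dataclass
class ComparatorConfig:
    """Settings for one baseline method."""

    method: str = "knn"
    B: int = 1001
    subset_size: int | None = None
    k_grid: tuple = tuple(range(1, 11))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {_METHODS}")
        if self.B < 1:
            raise ValueError("B must be >= 1")


def _force_odd(B: int) -> int:
    if B % 2 == 0:
        logger.warning("B=%d is even; using %d to keep votes tie-free", B, B + 1)
        return B + 1
    return B


def knn_predict(train: Dataset, test: np.ndarray, k_grid=range(1, 11),
                seed: int | np.random.Generator = 0, k: int | None = None) -> np.ndarray:
    """Plain kNN labels for the test rows; k is chosen by stratified
    cross-validation on the training set unless supplied."""
    if k is None:
        k = select_k_cv(train, k_grid, seed=seed)
    probs = _knn_prob(train.features, train.labels, np.atleast_2d(test), k)
    return classify_from_probability(probs)


def _bootstrap_knn_class1_counts(order: np.ndarray, ylab: np.ndarray,
                                 counts: np.ndarray, k: int) -> np.ndarray:
    """Class-1 count among the k nearest in-bag rows of each test point.

    ``order`` is the (n_test, n_train) neighbour order on the full
    training set, ``ylab`` the labels in that order, and ``counts`` the
    bootstrap multiplicity of each training row.  Walking the sorted
    order with cumulative multiplicities gives exactly the k-NN of the
    bootstrap multiset (duplicate rows are adjacent in the sort, and the
    lowest-index tie rule carries over).  Only a prefix of the order is
    scanned, widening in the rare case it holds fewer than k in-bag rows.
    """
    n_test, n_train = order.shape
    M = min(n_train, max(4 * k, 32))
    while True:
        c = counts[order[:, :M]]
        cum = np.cumsum(c, axis=1)
        if M < n_train and np.any(cum[:, -1] < k):
            M = min(n_train, 2 * M)
            continue
        break
    y1 = ylab[:, :M] * c
    cum1 = np.cumsum(y1, axis=1)
    j = (cum < k).sum(axis=1)  # first column where cumulative count >= k
    rows = np.arange(n_test)
    total = cum[rows, j]
    count1 = cum1[rows, j]
    overshoot = total - k  # surplus copies all belong to the boundary row
    count1 = count1 - overshoot * ylab[rows, j]
    return count1


def bagged_knn_predict(train: Dataset, test: np.ndarray, B: int = 1001,
                       k: int = 5, rng: np.random.Generator | None = None) -> np.ndarray:
    """Bagged kNN: B bootstrap resamples of the rows, full feature set,
    per-member kNN vote at the 0.5 cut-off, majority label."""
    rng = as_rng(rng)
    B = _force_odd(B)
    test = np.atleast_2d(test)
    order = _neighbor_order(train.features, test)
    ylab = train.labels[order]
    votes = np.zeros(test.shape[0], dtype=int)
    for _ in range(B):
        inbag = rng.integers(0, train.n, size=train.n)
        counts = np.bincount(inbag, minlength=train.n)
        count1 = _bootstrap_knn_class1_counts(order, ylab, counts, k)
        votes += (2 * count1 > k).astype(int)
    return (2 * votes > B).astype(int)


def _subspace_vote_predict(train: Dataset, test: np.ndarray, B: int,
                           subset_size: int | None, k: int,
                           rng: np.random.Generator, replace: bool) -> np.ndarray:
    rng = as_rng(rng)
    B = _force_odd(B)
    test = np.atleast_2d(test)
    l = subset_size if subset_size is not None else max(2, train.d // 3)
    votes = np.zeros(test.shape[0], dtype=int)
    # members with the same (multi)set of features predict identically,
    # so cache votes per distinct subset — a large saving when d is small
    cache: dict = {}
    for _ in range(B):
        if replace:
            subset = rng.choice(train.d, size=l, replace=True)
        else:
            subset = draw_feature_subset(train.d, l, rng)
        key = tuple(np.sort(subset))
        if key not in cache:
            probs = _knn_prob(train.features[:, subset], train.labels, test[:, subset], k)
            cache[key] = (probs > 0.5).astype(int)
        votes += cache[key]
    return (2 * votes > B).astype(int)


def random_knn_predict(train: Dataset, test: np.ndarray, B: int = 1001,
                       subset_size: int | None = None, k: int = 5,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Random kNN: each member sees a feature subset drawn without
    replacement and all training rows; members vote."""
    return _subspace_vote_predict(train, test, B, subset_size, k, rng, replace=False)


def mfs_knn_predict(train: Dataset, test: np.ndarray, B: int = 1001,
                    subset_size: int | None = None, k: int = 5,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Multiple-feature-subsets kNN: as random kNN but subsets are drawn
    with replacement, so a member may weight a feature twice."""
    return _subspace_vote_predict(train, test, B, subset_size, k, rng, replace=True)


def external_comparator_predict(method: str, train: Dataset, test: np.ndarray,
                                config: ComparatorConfig | None = None) -> np.ndarray:
    """Random forest or SVM labels via scikit-learn (optional extra).

    These are reference methods, delegated to an established
    implementation rather than re-built here.
    """
    if method not in ("rf", "svm"):
        raise ValueError(f"unknown external method {method!r}")
    if config is None:
        config = ComparatorConfig(method=method)
    try:
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.svm import SVC
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "scikit-learn is required for the rf/svm comparators; "
            "install the 'comparators' extra"
        ) from exc
    test = np.atleast_2d(test)
    if method == "rf":
        clf = RandomForestClassifier(n_estimators=500, random_state=config.seed)
    else:
        clf = SVC(kernel="rbf", gamma="scale", random_state=config.seed)
    clf.fit(train.features, train.labels)
    return clf.predict(test).astype(int)
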