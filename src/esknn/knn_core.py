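"""Core k-nearest-neighbour machinery: distances, class-probability
estimation, cross-validated choice of k, and stratified dataset splitting.

Everything downstream (the subset-kNN ensemble and the kNN-family
baselines) is built on the primitives in this module.  Distances are
plain Euclidean on unscaled features; an optional z-scoring helper is
provided for users whose features live on very different scales, but it
is never applied implicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "SplitPair",
    "load_csv",
    "save_csv",
    "standardize",
    "pairwise_distances",
    "knn_class1_probability",
    "classify_from_probability",
    "select_k_cv",
    "train_test_split",
    "split_construction_validation",
]


@dataclass
class Dataset:
    """A tabular two-class dataset: an ``(n, d)`` feature matrix and a
    length-``n`` vector of 0/1 labels.

    Parameters
    ----------
    features
        Real-valued feature matrix, one row per observation.
    labels
        Integer class labels, each 0 or 1.
    feature_names
        Optional column identifiers (length ``d``).
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-d array")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on n")
        if self.n < 1 or self.d < 1:
            raise ValueError("dataset needs at least one row and one column")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain NaN or infinite entries")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        if self.feature_names is not None and len(self.feature_names) != self.d:
            raise ValueError("feature_names length must equal d")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def take(self, rows: np.ndarray) -> "Dataset":
        """Row subset (or bootstrap multiset) as a new Dataset."""
        rows = np.asarray(rows, dtype=int)
        return Dataset(self.features[rows], self.labels[rows], self.feature_names)

    def select_features(self, cols: np.ndarray) -> "Dataset":
        """Column subset as a new Dataset (duplicates allowed)."""
        cols = np.asarray(cols, dtype=int)
        names = None
        if self.feature_names is not None:
            names = [self.feature_names[c] for c in cols]
        return Dataset(self.features[:, cols], self.labels, names)

    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))


@dataclass
class SplitPair:
    """Two disjoint row-subsets of a parent dataset whose index sets
    partition the parent's rows."""

    first: Dataset
    second: Dataset
    first_indices: np.ndarray
    second_indices: np.ndarray

    def __post_init__(self) -> None:
        a = set(self.first_indices.tolist())
        b = set(self.second_indices.tolist())
        if a & b:
            raise ValueError("split index sets overlap")


def load_csv(path, label_col: str | None = None) -> Dataset:
    """Read a delimited text file (header row required) into a Dataset.

    ``label_col`` names the label column; when omitted the last column is
    used.  Labels may be 0/1 integers or exactly two distinct strings,
    which are mapped alphabetically to 0/1 (the mapping is logged).  Rows
    with missing entries are dropped with a logged count.
    """
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError("need at least one feature column and one label column")
    if label_col is None:
        label_col = frame.columns[-1]
    if label_col not in frame.columns:
        raise ValueError(f"label column {label_col!r} not found")
    n_missing = int(frame.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d rows with missing values", n_missing)
        frame = frame.dropna(axis=0)
    if frame.empty:
        raise ValueError("no complete rows left after dropping missing values")
    raw = frame[label_col]
    if raw.dtype.kind in "iuf":
        labels = raw.to_numpy()
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("numeric labels must be 0 or 1")
        labels = labels.astype(int)
    else:
        levels = sorted(raw.astype(str).unique())
        if len(levels) != 2:
            raise ValueError(f"expected exactly 2 label levels, got {levels}")
        mapping = {levels[0]: 0, levels[1]: 1}
        logger.info("label mapping: %s", mapping)
        labels = raw.astype(str).map(mapping).to_numpy()
    feats = frame.drop(columns=[label_col])
    try:
        X = feats.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError("non-numeric feature column encountered") from exc
    return Dataset(X, labels, feature_names=list(feats.columns))


def save_csv(data: Dataset, path, label_col: str = "class") -> None:
    """Write a Dataset in the CSV dialect `load_csv` consumes."""
    names = data.feature_names or [f"x{j + 1}" for j in range(data.d)]
    frame = pd.DataFrame(data.features, columns=names)
    frame[label_col] = data.labels
    frame.to_csv(path, index=False)


def standardize(train: Dataset, *others: Dataset) -> tuple[Dataset, ...]:
    """z-score features using the training set's mean and standard
    deviation; constant columns are left centred.  Returns transformed
    copies of ``train`` and every dataset in ``others``."""
    mu = train.features.mean(axis=0)
    sd = train.features.std(axis=0)
    sd[sd == 0] = 1.0
    out = []
    for ds in (train, *others):
        out.append(Dataset((ds.features - mu) / sd, ds.labels, ds.feature_names))
    return tuple(out)


def as_rng(seed) -> np.random.Generator:
    """Pass through anything generator-like (anything offering
    ``integers``), otherwise build a fresh seeded Generator."""
    if hasattr(seed, "integers"):
        return seed
    return np.random.default_rng(seed)


def pairwise_distances(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between the rows of ``A`` and ``B``."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("point sets differ in dimension")
    return cdist(A, B, metric="euclidean")


def _neighbor_order(train_X: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Training indices sorted by distance for each query row; distance
    ties resolve to the lowest training index (stable sort)."""
    D = pairwise_distances(queries, train_X)
    return np.argsort(D, axis=1, kind="stable")


def _knn_prob(train_X: np.ndarray, train_y: np.ndarray,
              queries: np.ndarray, k: int) -> np.ndarray:
    n = train_X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= {n}, got {k}")
    if k == n:
        return np.full(queries.shape[0], train_y.mean())
    D = pairwise_distances(queries, train_X)
    # partial selection of the k nearest; a full stable sort is only
    # needed for rows where a distance tie straddles the k-th rank,
    # so the lowest-training-index tie rule still holds exactly
    part = np.argpartition(D, k - 1, axis=1)[:, :k]
    counts = train_y[part].sum(axis=1)
    thresh = np.take_along_axis(D, part, axis=1).max(axis=1)
    boundary_ties = np.flatnonzero((D <= thresh[:, None]).sum(axis=1) > k)
    for i in boundary_ties:
        order = np.argsort(D[i], kind="stable")
        counts[i] = train_y[order[:k]].sum()
    return counts / k


def _knn_prob_multi_k(train_X: np.ndarray, train_y: np.ndarray,
                      queries: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Class-1 probabilities for several k at the cost of one sort.

    Returns an array of shape ``(len(ks), n_queries)``.
    """
    ks = np.asarray(ks, dtype=int)
    if ks.size == 0:
        raise ValueError("empty k grid")
    if ks.max() > train_X.shape[0] or ks.min() < 1:
        raise ValueError("k out of range for training size")
    order = _neighbor_order(train_X, queries)
    kmax = int(ks.max())
    cum = np.cumsum(train_y[order[:, :kmax]], axis=1)  # (nq, kmax)
    return cum[:, ks - 1].T / ks[:, None]


def knn_class1_probability(train: Dataset, queries: np.ndarray, k: int) -> np.ndarray:
    """Fraction of class-1 labels among the k nearest training points of
    each query; always an integer multiple of 1/k."""
    return _knn_prob(train.features, train.labels, np.atleast_2d(queries), k)


def classify_from_probability(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Label 1 iff the class-1 probability strictly exceeds the cut-off
    (default 0.5); a probability exactly at the cut-off yields class 0."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(probs) > threshold).astype(int)


def _stratified_folds(labels: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold assignment (length n, values 0..n_folds-1), stratified by
    label: each class is shuffled and dealt round-robin."""
    fold = np.empty(labels.shape[0], dtype=int)
    for c in (0, 1):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def select_k_cv(train: Dataset, k_grid=range(1, 11), folds: int = 10,
                seed: int | np.random.Generator = 0) -> int:
    """Choose k by stratified cross-validation on the training set.

    Returns the k in ``k_grid`` minimising the mean fold misclassification
    rate under the 0.5 cut-off; ties go to the smallest k.
    """
    ks = np.sort(np.unique(np.asarray(list(k_grid), dtype=int)))
    if ks.size == 0:
        raise ValueError("empty k grid")
    if train.n < folds:
        raise ValueError("fewer observations than folds")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fold = _stratified_folds(train.labels, folds, rng)
    errs = np.zeros((ks.size, folds))
    for f in range(folds):
        hold = fold == f
        fit_X, fit_y = train.features[~hold], train.labels[~hold]
        if ks.max() > fit_X.shape[0]:
            raise ValueError("max(k_grid) exceeds fold training size")
        probs = _knn_prob_multi_k(fit_X, fit_y, train.features[hold], ks)
        pred = (probs > 0.5).astype(int)
        errs[:, f] = (pred != train.labels[hold]).mean(axis=1)
    mean_err = errs.mean(axis=1)
    return int(ks[int(np.argmin(mean_err))])  # argmin takes first → smallest k


def _stratified_partition(labels: np.ndarray, second_fraction: float,
                          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Split row indices into two stratified parts; the second part has
    round(n * second_fraction) rows overall, apportioned to classes by
    largest remainder."""
    n = labels.shape[0]
    n_second = int(round(n * second_fraction))
    classes = [np.flatnonzero(labels == c) for c in (0, 1)]
    for idx in classes:
        if idx.size < 2:
            raise ValueError("each class needs at least 2 members to split")
    ideals = [idx.size * second_fraction for idx in classes]
    counts = [int(np.floor(v)) for v in ideals]
    # distribute the remainder, then clamp so both sides keep both classes
    rema = np.array([v - c for v, c in zip(ideals, counts)])
    while sum(counts) < n_second:
        j = int(np.argmax(rema))
        counts[j] += 1
        rema[j] = -1.0
    for j, idx in enumerate(classes):
        counts[j] = min(max(counts[j], 1), idx.size - 1)
    second_parts, first_parts = [], []
    for idx, c in zip(classes, counts):
        perm = rng.permutation(idx)
        second_parts.append(perm[:c])
        first_parts.append(perm[c:])
    first = np.sort(np.concatenate(first_parts))
    second = np.sort(np.concatenate(second_parts))
    return first, second


def train_test_split(data: Dataset, test_fraction: float = 0.1,
                     seed: int | np.random.Generator = 0) -> SplitPair:
    """Stratified train/test split; ``second`` is the test part with
    round(n * test_fraction) rows.  Deterministic under a fixed seed."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tr, te = _stratified_partition(data.labels, test_fraction, rng)
    return SplitPair(data.take(tr), data.take(te), tr, te)


def split_construction_validation(train: Dataset, validation_fraction: float = 0.3,
                                  seed: int | np.random.Generator = 0) -> SplitPair:
    """Stratified split of the training data into a construction part
    (for building base classifiers) and a validation part (for the
    greedy ensemble-growth stage)."""
    return train_test_split(train, test_fraction=validation_fraction, seed=seed)
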