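"""Synthetic two-class generators used to benchmark the ensembles.

Model 1: class 1 is multivariate normal with mean 2 and an AR(1)-style
covariance ``w * Psi`` (``Psi[i, j] = (1/2)**|i-j|``), class 2 has
independent N(1, 1) features; the classes therefore differ in location
and in correlation structure, and ``w`` scales class 1's dispersion.

Model 2: four features uniform on [0, 100]; the class-1 probability
depends only on the Euclidean distance ``r`` of the point from a fixed
central point — 1 inside ``r < 110``, a linear ramp ``(150 - r) / 140``
for ``110 <= r <= 140``, 0 beyond.  Labels are Bernoulli draws from
that probability.

Both models can append label-independent noise features to stress-test
classifiers against non-informative inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .knn_core import Dataset, as_rng

__all__ = [
    "Model1Spec",
    "Model2Spec",
    "make_psi",
    "simulate_model1",
    "simulate_model2",
    "model2_class1_probability",
    "add_noise_features",
]


@dataclass
class Model1Spec:
    """Correlated-vs-independent Gaussian classes.

    ``n1``/``n2`` are per-class sample counts (the sources describing
    this design do not fix them; 500 + 500 gives datasets of 1000 rows,
    the same scale as model 2).  ``w`` multiplies class 1's covariance.
    """

    n1: int = 500
    n2: int = 500
    d: int = 20
    w: float = 1.0
    n_noise: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1 or self.d < 1:
            raise ValueError("n1, n2 and d must be >= 1")
        if self.w <= 0:
            raise ValueError("w must be positive")
        if self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")


@dataclass
class Model2Spec:
    """Distance-band Bernoulli model on the [0, 100]^4 hypercube.

    The central point defaults to the origin: distances from the origin
    have root-mean-square about 115, which places a sizeable share of
    points in each branch of the probability band and yields
    near-balanced classes.  (Measuring from the cube's centre would put
    every point inside r < 110 and make all labels 1.)
    """

    n: int = 1000
    central_point: tuple = (0.0, 0.0, 0.0, 0.0)
    n_noise: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if len(self.central_point) != 4:
            raise ValueError("central_point must have 4 coordinates")
        if self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")


def make_psi(d: int) -> np.ndarray:
    """The d x d matrix with entries (1/2)**|i-j|: unit diagonal,
    geometrically decaying off-diagonals, symmetric positive definite."""
    if d < 1:
        raise ValueError("d must be >= 1")
    idx = np.arange(d)
    return 0.5 ** np.abs(idx[:, None] - idx[None, :])


def add_noise_features(data: Dataset, count: int, family: str = "standard_normal",
                       rng: np.random.Generator | None = None) -> Dataset:
    """Append ``count`` label-independent columns drawn from the given
    family (``standard_normal`` or ``uniform_0_100``); labels unchanged."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if count == 0:
        return Dataset(data.features.copy(), data.labels.copy(), data.feature_names)
    rng = as_rng(rng)
    if family == "standard_normal":
        noise = rng.standard_normal((data.n, count))
    elif family == "uniform_0_100":
        noise = rng.uniform(0.0, 100.0, size=(data.n, count))
    else:
        raise ValueError(f"unknown noise family {family!r}")
    names = None
    if data.feature_names is not None:
        names = data.feature_names + [f"noise{j + 1}" for j in range(count)]
    return Dataset(np.hstack([data.features, noise]), data.labels.copy(), names)


def simulate_model1(spec: Model1Spec) -> Dataset:
    """Draw one model-1 dataset: class-1 rows ~ N(2 * 1_d, w * Psi),
    class-2 rows have d iid N(1, 1) features, labels 1/0 respectively,
    plus ``n_noise`` standard-normal noise columns."""
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(spec.w * make_psi(spec.d))
    class1 = 2.0 + rng.standard_normal((spec.n1, spec.d)) @ L.T
    class2 = rng.normal(1.0, 1.0, size=(spec.n2, spec.d))
    X = np.vstack([class1, class2])
    y = np.concatenate([np.ones(spec.n1, dtype=int), np.zeros(spec.n2, dtype=int)])
    names = [f"x{j + 1}" for j in range(spec.d)]
    data = Dataset(X, y, names)
    return add_noise_features(data, spec.n_noise, "standard_normal", rng)


def model2_class1_probability(r: np.ndarray) -> np.ndarray:
    """Class-1 probability as a function of the distance r from the
    central point: 1 below 110, (150 - r)/140 on [110, 140], 0 above."""
    r = np.asarray(r, dtype=float)
    return np.where(r < 110.0, 1.0,
                    np.where(r <= 140.0, (150.0 - r) / 140.0, 0.0))


def simulate_model2(spec: Model2Spec) -> Dataset:
    """Draw one model-2 dataset: 4 uniform features, Bernoulli labels
    from the distance-band probability, plus ``n_noise`` uniform noise
    columns."""
    rng = np.random.default_rng(spec.seed)
    X = rng.uniform(0.0, 100.0, size=(spec.n, 4))
    r = np.linalg.norm(X - np.asarray(spec.central_point, dtype=float), axis=1)
    p = model2_class1_probability(r)
    y = rng.binomial(1, p).astype(int)
    names = [f"x{j + 1}" for j in range(4)]
    data = Dataset(X, y, names)
    return add_noise_features(data, spec.n_noise, "uniform_0_100", rng)
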