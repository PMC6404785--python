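"""Ensemble of a subset of kNN classifiers (ESkNN).

The method builds ``m`` base kNN learners, each trained on a bootstrap
resample of the construction data restricted to a random feature subset
of size ``l``.  Stage one ranks the ``m`` learners by out-of-bag (OOB)
accuracy and keeps the top ``h``.  Stage two grows the final ensemble
greedily: starting from the best-ranked learner, each further candidate
joins only if the Brier score of the averaged-probability ensemble on a
held-out validation set strictly decreases.  Because the Brier score
rewards sharper probability estimates even when the predicted label does
not change, it can detect a candidate's contribution where the
misclassification rate cannot.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .knn_core import (
    Dataset,
    _knn_prob,
    classify_from_probability,
    select_k_cv,
    split_construction_validation,
)
from .metrics import brier_score, misclassification_rate

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleConfig",
    "BaseModel",
    "Ensemble",
    "draw_feature_subset",
    "draw_bootstrap",
    "build_base_models",
    "rank_and_select",
    "member_validation_probabilities",
    "greedy_select_from_probabilities",
    "greedy_brier_selection",
    "ensemble_predict_proba",
    "ensemble_predict",
    "fit_esknn",
    "save_ensemble",
    "load_ensemble",
]


@dataclass
class EnsembleConfig:
    """Tuning knobs of the two-stage ensemble.

    Parameters
    ----------
    m
        Number of base learners generated (forced odd so that votes over
        base learners cannot tie; an even value is bumped by one with a
        warning).
    subset_size
        Features per base learner, ``l``.  ``None`` resolves to
        ``max(2, d // 3)``: one third of the inputs, but never below two.
    reselect_fraction
        Fraction of the ``m`` learners kept after the OOB-accuracy
        ranking; ``h = max(1, floor(reselect_fraction * m))``.
    validation_fraction
        Share of the training data held out for the greedy Brier stage.
    k_grid
        Candidate neighbour counts for the cross-validated choice of k.
    combine_rule
        ``mean_prob`` (average member probabilities, threshold at 0.5) or
        ``majority_vote`` (each member votes its label).
    seed
        Seed controlling the split, the CV folds and all resampling.
    """

    m: int = 1001
    subset_size: int | None = None
    reselect_fraction: float = 0.4
    validation_fraction: float = 0.3
    k_grid: tuple = tuple(range(1, 11))
    combine_rule: str = "mean_prob"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.m % 2 == 0:
            logger.warning("m=%d is even; using %d to keep votes tie-free", self.m, self.m + 1)
            self.m += 1
        if not 0.0 < self.reselect_fraction <= 1.0:
            raise ValueError("reselect_fraction must lie in (0, 1]")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.combine_rule not in ("mean_prob", "majority_vote"):
            raise ValueError(f"unknown combine rule {self.combine_rule!r}")

    @property
    def h(self) -> int:
        """Number of learners surviving the OOB-accuracy stage."""
        return max(1, math.floor(self.reselect_fraction * self.m))

    def resolve_subset_size(self, d: int) -> int:
        l = self.subset_size if self.subset_size is not None else max(2, d // 3)
        if not 2 <= l <= d:
            raise ValueError(f"subset size must satisfy 2 <= l <= {d}, got {l}")
        return l


@dataclass
class BaseModel:
    """One subset-kNN ensemble member.

    ``feature_indices`` is its random feature subset, ``inbag_indices``
    the bootstrap multiset of construction rows it trains on (length n,
    with repeats), ``oob_indices`` the rows absent from the bootstrap,
    and ``oob_accuracy`` its accuracy predicting those rows.
    """

    feature_indices: np.ndarray
    inbag_indices: np.ndarray
    oob_indices: np.ndarray
    k: int
    oob_accuracy: float

    def predict_proba(self, construction: Dataset, queries: np.ndarray) -> np.ndarray:
        """Class-1 probability for each query row, using only this
        member's bootstrap rows and feature subset."""
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        if queries.shape[1] != construction.d:
            raise ValueError("query dimension does not match construction data")
        X = construction.features[np.ix_(self.inbag_indices, self.feature_indices)]
        y = construction.labels[self.inbag_indices]
        return _knn_prob(X, y, queries[:, self.feature_indices], self.k)


@dataclass
class Ensemble:
    """The accepted members in rank order, the construction data they
    index into, and the validation Brier trace of the accepted states
    (strictly decreasing by construction)."""

    members: list
    construction: Dataset
    k: int
    brier_trace: list = field(default_factory=list)
    config: EnsembleConfig | None = None

    def predict_proba(self, queries: np.ndarray) -> np.ndarray:
        return ensemble_predict_proba(self, queries)

    def predict(self, queries: np.ndarray, rule: str | None = None) -> np.ndarray:
        if rule is None:
            rule = self.config.combine_rule if self.config is not None else "mean_prob"
        return ensemble_predict(self, queries, rule)


def draw_feature_subset(d: int, l: int, rng: np.random.Generator) -> np.ndarray:
    """l distinct feature indices drawn uniformly without replacement."""
    if not 2 <= l <= d:
        raise ValueError(f"subset size must satisfy 2 <= l <= {d}, got {l}")
    return np.sort(rng.choice(d, size=l, replace=False))


def draw_bootstrap(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap multiset of size n (with replacement) and the
    out-of-bag complement.  On average about 36.8% of rows are OOB."""
    if n < 1:
        raise ValueError("n must be >= 1")
    inbag = rng.integers(0, n, size=n)
    oob = np.setdiff1d(np.arange(n), inbag)
    return inbag, oob


def build_base_models(construction: Dataset, config: EnsembleConfig, k: int,
                      rng: np.random.Generator) -> list[BaseModel]:
    """Generate the m base learners and score each on its own OOB rows.

    A learner whose bootstrap happens to cover every row has no OOB
    sample; it receives accuracy 0 (with a warning) rather than being
    redrawn, which keeps the stream of random draws simple.
    """
    if min(construction.class_counts()) < 1:
        raise ValueError("construction data must contain both classes")
    l = config.resolve_subset_size(construction.d)
    models = []
    for _ in range(config.m):
        subset = draw_feature_subset(construction.d, l, rng)
        inbag, oob = draw_bootstrap(construction.n, rng)
        model = BaseModel(subset, inbag, oob, k=k, oob_accuracy=0.0)
        if oob.size == 0:
            logger.warning("bootstrap left no OOB rows; member scored 0")
        else:
            probs = model.predict_proba(construction, construction.features[oob])
            pred = classify_from_probability(probs)
            model.oob_accuracy = 1.0 - misclassification_rate(construction.labels[oob], pred)
        models.append(model)
    return models


def rank_and_select(models: list[BaseModel], reselect_fraction: float) -> list[BaseModel]:
    """Top ``h = max(1, floor(fraction * m))`` learners by descending OOB
    accuracy; ties keep the original generation order (stable sort)."""
    if not models:
        raise ValueError("no models to rank")
    h = max(1, math.floor(reselect_fraction * len(models)))
    acc = np.array([m.oob_accuracy for m in models])
    order = np.argsort(-acc, kind="stable")
    return [models[i] for i in order[:h]]


def member_validation_probabilities(ranked: list[BaseModel], construction: Dataset,
                                    queries: np.ndarray) -> np.ndarray:
    """(h, n_queries) matrix of each ranked member's class-1 probability."""
    return np.vstack([m.predict_proba(construction, queries) for m in ranked])


def greedy_select_from_probabilities(member_probs: np.ndarray,
                                     y_val: np.ndarray) -> tuple[list[int], list[float]]:
    """Greedy forward pass over ranked members given their validation
    probabilities.

    The best member is always in.  Each later candidate joins only if
    the validation Brier score of the averaged-probability ensemble
    strictly decreases; rejected candidates are discarded and the scan
    continues through the whole list.  Returns the accepted row indices
    and the Brier score after each accepted state.
    """
    member_probs = np.atleast_2d(member_probs)
    accepted = [0]
    prob_sum = member_probs[0].astype(float).copy()
    current = brier_score(y_val, prob_sum)
    trace = [current]
    for r in range(1, member_probs.shape[0]):
        cand = (prob_sum + member_probs[r]) / (len(accepted) + 1)
        bs = brier_score(y_val, cand)
        if bs < current:
            accepted.append(r)
            prob_sum += member_probs[r]
            current = bs
            trace.append(bs)
    return accepted, trace


def greedy_brier_selection(ranked: list[BaseModel], construction: Dataset,
                           validation: Dataset) -> Ensemble:
    """Stage two: grow the ensemble from the ranked learners under the
    strictly-decreasing validation Brier criterion."""
    if not ranked:
        raise ValueError("ranked model list is empty")
    if validation.n < 1:
        raise ValueError("validation set is empty")
    if min(validation.class_counts()) == 0:
        logger.warning("validation set contains a single class only")
    probs = member_validation_probabilities(ranked, construction, validation.features)
    accepted, trace = greedy_select_from_probabilities(probs, validation.labels)
    members = [ranked[i] for i in accepted]
    return Ensemble(members=members, construction=construction,
                    k=ranked[0].k, brier_trace=trace)


def ensemble_predict_proba(ensemble: Ensemble, queries: np.ndarray) -> np.ndarray:
    """Unweighted mean of the members' class-1 probabilities."""
    probs = member_validation_probabilities(ensemble.members, ensemble.construction,
                                            np.atleast_2d(queries))
    return probs.mean(axis=0)


def ensemble_predict(ensemble: Ensemble, queries: np.ndarray,
                     rule: str = "mean_prob") -> np.ndarray:
    """Final labels under the chosen combining rule.

    ``mean_prob`` thresholds the averaged probability at 0.5 (strict).
    ``majority_vote`` lets each member vote its thresholded label; an
    exact vote tie falls back to the mean-probability rule.
    """
    queries = np.atleast_2d(queries)
    if rule == "mean_prob":
        return classify_from_probability(ensemble_predict_proba(ensemble, queries))
    if rule == "majority_vote":
        probs = member_validation_probabilities(ensemble.members, ensemble.construction,
                                                queries)
        votes = (probs > 0.5).sum(axis=0)
        n_members = probs.shape[0]
        out = (votes * 2 > n_members).astype(int)
        tie = votes * 2 == n_members
        if np.any(tie):
            fallback = classify_from_probability(probs.mean(axis=0))
            out[tie] = fallback[tie]
        return out
    raise ValueError(f"unknown combine rule {rule!r}")


def fit_esknn(train: Dataset, config: EnsembleConfig | None = None) -> Ensemble:
    """Fit the full two-stage pipeline on a training set.

    Splits off a stratified validation part, picks k once by stratified
    cross-validation on the construction part (shared by every member),
    builds and ranks the m base learners, and runs the greedy Brier
    selection.  Deterministic under a fixed ``config.seed``.
    """
    if config is None:
        config = EnsembleConfig()
    rng = np.random.default_rng(config.seed)
    split = split_construction_validation(train, config.validation_fraction, rng)
    construction, validation = split.first, split.second
    k_grid = [k for k in config.k_grid if k <= construction.n]
    k = select_k_cv(construction, k_grid, seed=rng)
    models = build_base_models(construction, config, k, rng)
    ranked = rank_and_select(models, config.reselect_fraction)
    ensemble = greedy_brier_selection(ranked, construction, validation)
    ensemble.config = config
    return ensemble


def save_ensemble(ensemble: Ensemble, path) -> None:
    """Serialise a fitted ensemble (config, members and construction
    data) to JSON so prediction can run in a later process."""
    cfg = ensemble.config
    payload = {
        "k": ensemble.k,
        "brier_trace": list(map(float, ensemble.brier_trace)),
        "config": None if cfg is None else {
            "m": cfg.m,
            "subset_size": cfg.subset_size,
            "reselect_fraction": cfg.reselect_fraction,
            "validation_fraction": cfg.validation_fraction,
            "k_grid": list(cfg.k_grid),
            "combine_rule": cfg.combine_rule,
            "seed": cfg.seed,
        },
        "members": [
            {
                "feature_indices": m.feature_indices.tolist(),
                "inbag_indices": m.inbag_indices.tolist(),
                "oob_indices": m.oob_indices.tolist(),
                "k": m.k,
                "oob_accuracy": m.oob_accuracy,
            }
            for m in ensemble.members
        ],
        "construction": {
            "features": ensemble.construction.features.tolist(),
            "labels": ensemble.construction.labels.tolist(),
            "feature_names": ensemble.construction.feature_names,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_ensemble(path) -> Ensemble:
    with open(path) as fh:
        payload = json.load(fh)
    construction = Dataset(
        np.array(payload["construction"]["features"], dtype=float),
        np.array(payload["construction"]["labels"], dtype=int),
        payload["construction"]["feature_names"],
    )
    members = [
        BaseModel(
            feature_indices=np.array(m["feature_indices"], dtype=int),
            inbag_indices=np.array(m["inbag_indices"], dtype=int),
            oob_indices=np.array(m["oob_indices"], dtype=int),
            k=int(m["k"]),
            oob_accuracy=float(m["oob_accuracy"]),
        )
        for m in payload["members"]
    ]
    config = None
    if payload["config"] is not None:
        c = payload["config"]
        config = EnsembleConfig(
            m=c["m"], subset_size=c["subset_size"],
            reselect_fraction=c["reselect_fraction"],
            validation_fraction=c["validation_fraction"],
            k_grid=tuple(c["k_grid"]), combine_rule=c["combine_rule"],
            seed=c["seed"],
        )
    return Ensemble(members=members, construction=construction, k=int(payload["k"]),
                    brier_trace=list(payload["brier_trace"]), config=config)
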