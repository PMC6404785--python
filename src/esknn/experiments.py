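"""Benchmarking harness: repeated stratified train/test splits shared
across methods, and reduced-replication reproduction of the simulation
comparison tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import comparators
from .comparators import ComparatorConfig, external_comparator_predict
from .ensemble import EnsembleConfig, fit_esknn
from .knn_core import Dataset, select_k_cv, train_test_split
from .metrics import misclassification_rate
from .simulators import Model1Spec, Model2Spec, simulate_model1, simulate_model2

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ResultsTable", "run_comparison",
           "reproduce_simulation_table", "plot_error_vs_noise"]

KNN_FAMILY = ("knn", "bknn", "rknn", "mfs", "esknn")
ALL_METHODS = KNN_FAMILY + ("rf", "svm")


@dataclass
class ExperimentConfig:
    """One benchmarking run: which methods, how many resplits, and the
    shared ensemble settings.

    ``ensemble_size`` is the number of base learners: m for ESkNN and B
    for the bagged/subspace baselines.  k is chosen once per split by
    stratified cross-validation on the training part and shared by every
    kNN-family method, mirroring a protocol with one CV per method.
    """

    methods: tuple = ("knn", "esknn")
    n_splits: int = 1000
    test_fraction: float = 0.1
    ensemble_size: int = 1001
    subset_size: int | None = None
    k_grid: tuple = tuple(range(1, 11))
    reselect_fraction: float = 0.4
    validation_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if not self.methods:
            raise ValueError("methods list is empty")
        for m in self.methods:
            if m not in ALL_METHODS:
                raise ValueError(f"unknown method {m!r}; choose from {ALL_METHODS}")


@dataclass
class ResultsTable:
    """Per-split misclassification rates plus metadata; aggregates are
    always recomputable from the persisted per-split records."""

    per_split: pd.DataFrame  # columns: scenario, method, rep, split, rate, n_test
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Mean rate, standard error and count per (scenario, method)."""
        g = self.per_split.groupby(["scenario", "method"], sort=False)["rate"]
        out = g.agg(mean_rate="mean", n="size")
        out["se"] = g.std(ddof=1).fillna(0.0) / np.sqrt(out["n"])
        return out.reset_index()[["scenario", "method", "mean_rate", "se", "n"]]

    def to_tsv(self, path, per_split: bool = False) -> None:
        """Write the summary (or the per-split records) as a
        tab-separated table with a '#'-prefixed metadata header."""
        frame = self.per_split if per_split else self.summary()
        with open(path, "w") as fh:
            for key, val in self.meta.items():
                fh.write(f"# {key}: {val}\n")
            frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _child_int(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] & 0x7FFFFFFF)


def _predict_one(method: str, train: Dataset, test_X: np.ndarray, k: int,
                 config: ExperimentConfig, seq: np.random.SeedSequence) -> np.ndarray:
    rng = np.random.default_rng(seq)
    B = config.ensemble_size
    if method == "knn":
        return comparators.knn_predict(train, test_X, k=k)
    if method == "bknn":
        return comparators.bagged_knn_predict(train, test_X, B=B, k=k, rng=rng)
    if method == "rknn":
        return comparators.random_knn_predict(train, test_X, B=B,
                                              subset_size=config.subset_size, k=k, rng=rng)
    if method == "mfs":
        return comparators.mfs_knn_predict(train, test_X, B=B,
                                           subset_size=config.subset_size, k=k, rng=rng)
    if method == "esknn":
        ecfg = EnsembleConfig(m=B, subset_size=config.subset_size,
                              reselect_fraction=config.reselect_fraction,
                              validation_fraction=config.validation_fraction,
                              k_grid=config.k_grid, seed=_child_int(seq))
        return fit_esknn(train, ecfg).predict(test_X)
    if method in ("rf", "svm"):
        ccfg = ComparatorConfig(method=method, seed=_child_int(seq))
        return external_comparator_predict(method, train, test_X, ccfg)
    raise ValueError(f"unknown method {method!r}")


def run_comparison(data: Dataset, config: ExperimentConfig,
                   scenario: str = "data") -> ResultsTable:
    """Evaluate every configured method on ``n_splits`` shared
    stratified train/test partitions of one dataset.

    For each split every method sees the identical train/test indices;
    k is selected once on the training part and shared by the
    kNN-family methods.  Fully seeded and reproducible.
    """
    root = np.random.SeedSequence(config.seed)
    split_seqs = root.spawn(config.n_splits)
    rows = []
    for s, seq in enumerate(split_seqs):
        children = seq.spawn(2 + len(config.methods))
        split = train_test_split(data, config.test_fraction,
                                 np.random.default_rng(children[0]))
        train, test = split.first, split.second
        logger.debug("split %d: test indices %s", s, split.second_indices.tolist())
        k = None
        if any(m in KNN_FAMILY for m in config.methods):
            k_grid = [kk for kk in config.k_grid if kk <= train.n]
            k = select_k_cv(train, k_grid, seed=np.random.default_rng(children[1]))
        for j, method in enumerate(config.methods):
            pred = _predict_one(method, train, test.features, k, config, children[2 + j])
            rate = misclassification_rate(test.labels, pred)
            logger.debug("split %d method %s rate %.4f", s, method, rate)
            rows.append({"scenario": scenario, "method": method, "rep": 0,
                         "split": s, "rate": rate, "n_test": test.n})
    frame = pd.DataFrame(rows)
    meta = {"seed": config.seed, "n_splits": config.n_splits,
            "test_fraction": config.test_fraction,
            "ensemble_size": config.ensemble_size}
    return ResultsTable(frame, meta)


def _scenario_label(model: int, overrides: dict) -> str:
    base_d = 20 if model == 1 else 4
    noise = overrides.get("n_noise", 0)
    label = f"{base_d}+{noise}" if noise else str(base_d)
    if model == 1 and "w" in overrides:
        label += f",w={overrides['w']}"
    return label


def reproduce_simulation_table(model: int, scenarios: list[dict], reps: int,
                               methods: tuple, seed: int = 0,
                               **config_kw) -> ResultsTable:
    """Simulation comparison table at configurable replication.

    For each scenario (a dict of simulator-spec overrides, e.g.
    ``{"n_noise": 200}`` or ``{"w": 5, "n_noise": 50}``) this generates
    ``reps`` independent datasets, evaluates all methods on one shared
    stratified 90/10 split of each, and averages across datasets.
    """
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    root = np.random.SeedSequence(seed)
    frames = []
    for overrides in scenarios:
        label = _scenario_label(model, overrides)
        for rep in range(reps):
            child = root.spawn(1)[0]
            data_seed, run_seed = (_child_int(c) for c in child.spawn(2))
            if model == 1:
                data = simulate_model1(Model1Spec(seed=data_seed, **overrides))
            else:
                data = simulate_model2(Model2Spec(seed=data_seed, **overrides))
            cfg = ExperimentConfig(methods=tuple(methods), n_splits=1,
                                   seed=run_seed, **config_kw)
            table = run_comparison(data, cfg, scenario=label)
            table.per_split["rep"] = rep
            frames.append(table.per_split)
    frame = pd.concat(frames, ignore_index=True)
    meta = {"model": model, "reps": reps, "seed": seed,
            "methods": ",".join(methods)}
    meta.update(config_kw)
    return ResultsTable(frame, meta)


def plot_error_vs_noise(table: ResultsTable, path) -> None:
    """Mean error rate against the number of appended noise features,
    one line per method (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = table.summary()
    noise = summary["scenario"].str.extract(r"\+(\d+)").fillna(0).astype(int)[0]
    summary = summary.assign(noise=noise)
    fig, ax = plt.subplots(figsize=(6, 4))
    for method, grp in summary.groupby("method", sort=False):
        grp = grp.sort_values("noise")
        ax.errorbar(grp["noise"], grp["mean_rate"], yerr=grp["se"],
                    marker="o", capsize=3, label=method)
    ax.set_xlabel("added non-informative features")
    ax.set_ylabel("mean misclassification rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
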