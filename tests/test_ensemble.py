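import logging
from itertools import combinations

import numpy as np
import pytest

from conftest import make_blobs, make_random_dataset
from esknn.ensemble import (
    BaseModel,
    Ensemble,
    EnsembleConfig,
    build_base_models,
    draw_bootstrap,
    draw_feature_subset,
    ensemble_predict,
    ensemble_predict_proba,
    fit_esknn,
    greedy_brier_selection,
    greedy_select_from_probabilities,
    load_ensemble,
    rank_and_select,
    save_ensemble,
)
from esknn.knn_core import Dataset, train_test_split
from esknn.metrics import misclassification_rate

DUMMY = Dataset([[0.0, 0.0], [1.0, 1.0]], [0, 1])


class FixedProbModel(BaseModel):
    """Stub member returning a constant class-1 probability."""

    def __init__(self, prob, oob_accuracy=1.0):
        super().__init__(np.array([0, 1]), np.array([0, 1]), np.array([], dtype=int),
                         k=1, oob_accuracy=oob_accuracy)
        self._prob = prob

    def predict_proba(self, construction, queries):
        return np.full(np.atleast_2d(queries).shape[0], self._prob)


def fixed_ensemble(*probs):
    return Ensemble(members=[FixedProbModel(p) for p in probs],
                    construction=DUMMY, k=1)


class TestConfig:
    def test_even_m_bumped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            cfg = EnsembleConfig(m=10)
        assert cfg.m == 11

    def test_h_is_floor_of_fraction(self):
        assert EnsembleConfig(m=1001, reselect_fraction=0.4).h == 400
        assert EnsembleConfig(m=1, reselect_fraction=0.4).h == 1

    @pytest.mark.parametrize("kw", [{"reselect_fraction": 0.0}, {"validation_fraction": 1.0},
                                    {"combine_rule": "median"}, {"m": 0}])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            EnsembleConfig(**kw)


class TestFeatureSubset:
    def test_full_subset_is_all_indices(self, rng):
        assert draw_feature_subset(4, 4, rng).tolist() == [0, 1, 2, 3]

    @pytest.mark.parametrize("l", [1, 6])
    def test_out_of_range_size_raises(self, l, rng):
        with pytest.raises(ValueError):
            draw_feature_subset(5, l, rng)

    def test_uniform_over_pairs(self, rng):
        counts = {pair: 0 for pair in combinations(range(5), 2)}
        n_draws = 100_000
        for _ in range(n_draws):
            counts[tuple(draw_feature_subset(5, 2, rng))] += 1
        p = 1 / 10
        four_sigma = 4 * np.sqrt(p * (1 - p) / n_draws)
        for pair, c in counts.items():
            assert abs(c / n_draws - p) < four_sigma, pair


class TestBootstrap:
    def test_single_observation(self, rng):
        inbag, oob = draw_bootstrap(1, rng)
        assert inbag.tolist() == [0] and oob.size == 0

    def test_partition_property(self, rng):
        inbag, oob = draw_bootstrap(100, rng)
        assert inbag.size == 100
        combined = np.union1d(np.unique(inbag), oob)
        assert np.array_equal(combined, np.arange(100))

    def test_invalid_n_raises(self, rng):
        with pytest.raises(ValueError):
            draw_bootstrap(0, rng)


class _IdentityBootstrapRng:
    """Stub rng whose bootstrap is the identity sample (no OOB rows)."""

    def __init__(self):
        self._inner = np.random.default_rng(0)

    def choice(self, *args, **kwargs):
        return self._inner.choice(*args, **kwargs)

    def integers(self, low, high=None, size=None):
        return np.arange(size)


class TestBuildBaseModels:
    def test_builds_m_valid_models(self, rng):
        data = make_random_dataset(40, 6, seed=1)
        models = build_base_models(data, EnsembleConfig(m=3, seed=0), k=3, rng=rng)
        assert len(models) == 3
        for m in models:
            assert len(set(m.feature_indices.tolist())) == m.feature_indices.size
            assert not set(m.oob_indices) & set(m.inbag_indices)
            assert 0.0 <= m.oob_accuracy <= 1.0

    def test_empty_oob_scores_zero_with_warning(self, caplog):
        data = make_random_dataset(10, 4, seed=2)
        with caplog.at_level(logging.WARNING):
            models = build_base_models(data, EnsembleConfig(m=1, seed=0), k=1,
                                       rng=_IdentityBootstrapRng())
        assert models[0].oob_indices.size == 0
        assert models[0].oob_accuracy == 0.0
        assert "no OOB" in caplog.text

    def test_oob_accuracy_matches_recomputation(self, rng):
        data = make_random_dataset(60, 5, seed=3)
        (model,) = build_base_models(data, EnsembleConfig(m=1, seed=0), k=3, rng=rng)
        probs = model.predict_proba(data, data.features[model.oob_indices])
        pred = (probs > 0.5).astype(int)
        expected = 1.0 - misclassification_rate(data.labels[model.oob_indices], pred)
        assert model.oob_accuracy == pytest.approx(expected)

    def test_single_class_construction_raises(self, rng):
        data = Dataset(np.zeros((5, 3)), [1, 1, 1, 1, 1])
        with pytest.raises(ValueError):
            build_base_models(data, EnsembleConfig(m=1), k=1, rng=rng)


class TestRankAndSelect:
    def test_keeps_best_of_three(self):
        models = [FixedProbModel(0.5, a) for a in (0.6, 0.9, 0.7)]
        top = rank_and_select(models, 0.4)  # h = floor(1.2) = 1
        assert len(top) == 1 and top[0].oob_accuracy == 0.9

    def test_ties_keep_generation_order(self):
        models = [FixedProbModel(p, 0.5) for p in (0.1, 0.2, 0.3, 0.4, 0.5)]
        top = rank_and_select(models, 0.5)  # h = 2
        assert [m._prob for m in top] == [0.1, 0.2]

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            rank_and_select([], 0.4)


class TestGreedySelection:
    def test_worked_three_classifier_example(self):
        probs = np.array([[0.56], [0.68], [0.88]])
        accepted, trace = greedy_select_from_probabilities(probs, np.array([1]))
        assert accepted == [0, 1, 2]
        assert trace[0] == pytest.approx(0.1936, abs=1e-12)
        assert trace[1] == pytest.approx(0.1444, abs=1e-12)
        assert trace[2] == pytest.approx((1 - 2.12 / 3) ** 2, abs=1e-12)

    def test_worsening_candidate_rejected_scan_continues(self):
        # third candidate drags the mean to 0.44667 → Brier worsens → rejected
        probs = np.array([[0.56], [0.68], [0.10]])
        accepted, trace = greedy_select_from_probabilities(probs, np.array([1]))
        assert accepted == [0, 1]
        assert len(trace) == 2

    def test_rejected_candidate_does_not_block_later_ones(self):
        probs = np.array([[0.56], [0.68], [0.10], [0.90]])
        accepted, _ = greedy_select_from_probabilities(probs, np.array([1]))
        assert accepted == [0, 1, 3]

    def test_single_candidate(self):
        accepted, trace = greedy_select_from_probabilities(np.array([[0.9]]), np.array([1]))
        assert accepted == [0] and len(trace) == 1

    def test_on_datasets_trace_strictly_decreasing(self):
        data = make_random_dataset(80, 6, seed=5)
        split = train_test_split(data, 0.3, seed=1)
        models = build_base_models(split.first, EnsembleConfig(m=21, seed=0), k=3,
                                   rng=np.random.default_rng(7))
        ranked = rank_and_select(models, 0.5)
        ens = greedy_brier_selection(ranked, split.first, split.second)
        assert all(b < a for a, b in zip(ens.brier_trace, ens.brier_trace[1:]))
        assert ens.members[0] is ranked[0]
        assert 1 <= len(ens.members) <= len(ranked)

    def test_empty_ranked_list_raises(self):
        with pytest.raises(ValueError):
            greedy_brier_selection([], DUMMY, DUMMY)

    def test_empty_validation_unrepresentable(self):
        # an empty validation set is rejected at construction time
        with pytest.raises(ValueError):
            Dataset(np.empty((0, 2)), np.empty(0, dtype=int))


class TestEnsemblePrediction:
    def test_mean_of_two_members(self):
        ens = fixed_ensemble(0.56, 0.68)
        assert ensemble_predict_proba(ens, [[0.0, 0.0]]) == pytest.approx([0.62])

    def test_single_member_passthrough(self):
        ens = fixed_ensemble(0.56)
        assert ensemble_predict_proba(ens, [[0.0, 0.0]]) == pytest.approx([0.56])

    def test_three_member_mean(self):
        ens = fixed_ensemble(0.56, 0.68, 0.88)
        prob = ensemble_predict_proba(ens, [[0.0, 0.0]])[0]
        assert prob == pytest.approx(0.706667, abs=1e-6)
        assert round(prob, 2) == 0.71

    def test_mean_prob_rule_thresholds(self):
        ens = fixed_ensemble(0.56, 0.68)
        assert ensemble_predict(ens, [[0.0, 0.0]], "mean_prob").tolist() == [1]

    def test_all_members_negative(self):
        ens = fixed_ensemble(0.1, 0.2, 0.3)
        for rule in ("mean_prob", "majority_vote"):
            assert ensemble_predict(ens, [[0.0, 0.0]], rule).tolist() == [0]

    def test_vote_tie_falls_back_to_mean_probability(self):
        ens = fixed_ensemble(0.9, 0.0)  # votes 1/0, mean prob 0.45
        assert ensemble_predict(ens, [[0.0, 0.0]], "majority_vote").tolist() == [0]

    def test_unknown_rule_raises(self):
        with pytest.raises(ValueError):
            ensemble_predict(fixed_ensemble(0.5), [[0.0, 0.0]], "median")


class TestFitEsknn:
    def test_deterministic_under_seed(self):
        data = make_random_dataset(60, 6, seed=9)
        cfg = EnsembleConfig(m=11, seed=5)
        a = fit_esknn(data, cfg)
        b = fit_esknn(data, EnsembleConfig(m=11, seed=5))
        assert len(a.members) == len(b.members)
        for ma, mb in zip(a.members, b.members):
            assert np.array_equal(ma.feature_indices, mb.feature_indices)
            assert np.array_equal(ma.inbag_indices, mb.inbag_indices)

    def test_member_count_bounded_by_h(self):
        data = make_random_dataset(60, 6, seed=10)
        ens = fit_esknn(data, EnsembleConfig(m=5, seed=1))
        assert 1 <= len(ens.members) <= 2  # h = floor(0.4 * 5)

    def test_separable_data_classified_perfectly(self, separable):
        split = train_test_split(separable, 0.2, seed=3)
        ens = fit_esknn(split.first, EnsembleConfig(m=21, seed=2))
        pred = ens.predict(split.second.features)
        assert misclassification_rate(split.second.labels, pred) == 0.0

    def test_trace_strictly_decreasing(self):
        data = make_random_dataset(100, 8, seed=11)
        ens = fit_esknn(data, EnsembleConfig(m=31, seed=4))
        diffs = np.diff(ens.brier_trace)
        assert np.all(diffs < 0)


class TestPersistence:
    def test_round_trip_preserves_predictions(self, tmp_path):
        data = make_random_dataset(50, 5, seed=12)
        ens = fit_esknn(data, EnsembleConfig(m=11, seed=6))
        path = tmp_path / "model.json"
        save_ensemble(ens, path)
        loaded = load_ensemble(path)
        queries = np.random.default_rng(0).normal(size=(7, 5))
        assert np.array_equal(ens.predict_proba(queries), loaded.predict_proba(queries))
        assert loaded.config.m == ens.config.m
        assert loaded.brier_trace == pytest.approx(ens.brier_trace)
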