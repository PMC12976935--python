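import itertools

import numpy as np
import pytest

from funclust import benchmark, evaluation, training
from funclust.evaluation import (
    cooccurrence_clusters,
    grouping_agreement,
    jaccard,
    linear_on_groups,
    model_I,
    model_II,
    model_III,
    pca_linear_baseline,
    r_squared,
)
from funclust.io import RunConfig


def jaccard_oracle(truth_labels, pred_labels):
    """Independent loop-based recovery score: per truth group, the best
    intersection-over-union over predicted groups, then the mean."""
    truth_labels = np.asarray(truth_labels)
    pred_labels = np.asarray(pred_labels)
    scores = []
    for g in sorted(set(truth_labels.tolist())):
        ti = {i for i in range(len(truth_labels)) if truth_labels[i] == g}
        best = 0.0
        for h in sorted(set(pred_labels.tolist())):
            pj = {i for i in range(len(pred_labels)) if pred_labels[i] == h}
            best = max(best, len(ti & pj) / len(ti | pj))
        scores.append(best)
    return sum(scores) / len(scores)


class TestJaccard:
    def test_identical_groupings_score_one(self):
        labels = np.array([1, 1, 2, 2, 3, 3])
        cmp = jaccard(labels, labels)
        np.testing.assert_array_equal(cmp.per_group_jaccard, 1.0)
        assert cmp.total_jaccard == 1.0

    def test_three_element_overlap_case(self):
        # truth group {1,2,3} vs predicted group {2,3,4}: 2 shared of 4 total
        truth = {1: {1, 2, 3}, 2: {0, 4}}
        pred = {1: {2, 3, 4}, 2: {0, 1}}
        cmp = jaccard(truth, pred)
        assert cmp.per_group_jaccard[0] == pytest.approx(2 / 4)

    def test_disjoint_single_groups_score_zero(self):
        cmp = jaccard({1: {0, 1}}, {1: {2, 3}}, )
        assert cmp.total_jaccard == 0.0

    def test_sum_denominator_variant_halves_perfect_score(self):
        labels = np.array([1, 1, 2, 2])
        assert jaccard(labels, labels, sum_denominator=True).total_jaccard == 0.5

    def test_label_permutation_invariance(self, rng):
        truth = rng.integers(1, 4, size=12)
        pred = rng.integers(1, 4, size=12)
        relabeled = np.array([3, 1, 2])[pred - 1]
        assert jaccard(truth, pred).total_jaccard == jaccard(truth, relabeled).total_jaccard

    def test_exhaustive_three_group_partitions_of_six(self):
        """Exact agreement with the loop-based oracle on every assignment of
        6 features into up to 3 groups."""
        truth = np.array([1, 1, 2, 2, 3, 3])
        for assignment in itertools.product((1, 2, 3), repeat=6):
            pred = np.array(assignment)
            assert jaccard(truth, pred).total_jaccard == pytest.approx(
                jaccard_oracle(truth, pred)
            )

    def test_random_assignment_average_matches_independent_estimate(self):
        """Mean recovery of uniformly random 12-feature/3-group assignments,
        estimated twice with independent streams, agrees within 0.02."""
        truth = np.repeat([1, 2, 3], 4)

        def estimate(seed):
            r = np.random.default_rng(seed)
            vals = [
                jaccard_oracle(truth, r.integers(1, 4, size=12)) for _ in range(1000)
            ]
            return float(np.mean(vals))

        a = estimate(0)
        r = np.random.default_rng(1)
        b = float(np.mean([jaccard(truth, r.integers(1, 4, size=12)).total_jaccard
                           for _ in range(1000)]))
        assert abs(a - b) < 0.02

    def test_gated_features_scored_as_irrelevant_class(self):
        truth = np.array([1, 1, 2, 2, 0, 0])  # 0 = irrelevant
        pred = np.array([1, 1, 2, 2, 1, 2])
        active = np.array([True, True, True, True, False, False])
        cmp = jaccard(truth, pred, truth_irrelevant_label=0, predicted_active=active)
        assert cmp.total_jaccard == 1.0


class TestRSquared:
    def test_perfect_prediction(self, rng):
        y = rng.normal(size=(10, 2))
        assert r_squared(y, y) == 1.0

    def test_mean_predictor_scores_zero(self, rng):
        y = rng.normal(size=20)
        assert r_squared(y, np.full(20, y.mean())) == pytest.approx(0.0)

    def test_three_point_hand_case(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.array([1.0, 2.0, 2.0])
        # SSE = 1, SST = 2
        assert r_squared(obs, pred) == pytest.approx(1 - 1 / 2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            r_squared(np.ones(5), np.zeros(5))


class TestCooccurrenceModels:
    def test_duplicated_features_cluster_together(self, rng):
        base = rng.uniform(size=(60, 3))
        X = np.column_stack([base, base * 2.0])  # feature j+3 is collinear with j
        labels = cooccurrence_clusters(X, 3)
        for j in range(3):
            assert labels[j] == labels[j + 3]

    def test_function_blind(self, small_benchmark, rng):
        X, F, _ = small_benchmark
        tr, te = training.split_data(X.n_samples, 0.8, 0)
        lab1, _ = model_I(X.values, F.values, 3, tr, te)
        lab2, _ = model_I(X.values, rng.permutation(F.values), 3, tr, te)
        np.testing.assert_array_equal(lab1, lab2)

    def test_model_II_shares_model_I_clustering(self, small_benchmark):
        X, F, _ = small_benchmark
        tr, te = training.split_data(X.n_samples, 0.8, 0)
        cfg = RunConfig(hidden_layers=(8, 8), max_iters=300, early_stop_patience=100)
        lab1, r2_1 = model_I(X.values, F.values, 3, tr, te)
        lab2, r2_2 = model_II(X.values, F.values, 3, tr, te, cfg, seed=0)
        np.testing.assert_array_equal(lab1, lab2)
        assert r2_1 != r2_2

    def test_constant_feature_handled(self, rng):
        X = rng.uniform(size=(30, 4))
        X[:, 2] = 1.0
        labels = cooccurrence_clusters(X, 2)
        assert set(labels) <= {1, 2}


class TestModelIII:
    def test_zero_move_budget_returns_initial_grouping(self, small_benchmark):
        X, F, _ = small_benchmark
        tr, te = training.split_data(X.n_samples, 0.8, 0)
        lab, _ = model_III(X.values, F.values, 3, tr, te, n_moves=0, n_restarts=1, seed=5)
        expected = np.random.default_rng(5).integers(0, 3, size=X.n_features) + 1
        np.testing.assert_array_equal(lab, expected)

    def test_recovers_linear_truth(self):
        """A linear structure-function truth is inside Model III's class, so
        the annealed search should recover the true grouping."""
        v = (1.0, -0.5, -0.1)
        co = benchmark.RegimeCoefficients(a1=v, a2=v, a3=v)
        X, F, truth = benchmark.generate_benchmark(
            benchmark.BenchmarkSpec(n_samples=300, seed=8), co
        )
        tr, te = training.split_data(300, 0.8, 0)
        lab, r2 = model_III(X.values, F.values, 3, tr, te, n_moves=6000, n_restarts=2, seed=0)
        assert jaccard(truth["labels"], lab).total_jaccard >= 0.9
        assert r2 > 0.99


class TestPCABaseline:
    def test_full_rank_linear_function_perfectly_fit(self, rng):
        X = rng.uniform(size=(50, 4))
        w = rng.normal(size=4)
        F = (X @ w)[:, None]
        tr, te = training.split_data(50, 0.8, 0)
        assert pca_linear_baseline(X, F, 4, tr, te) == pytest.approx(1.0)

    def test_train_projections_uncorrelated(self, rng):
        from sklearn.decomposition import PCA

        X = rng.uniform(size=(80, 6))
        tr, _ = training.split_data(80, 0.8, 1)
        Z = PCA(n_components=3).fit_transform(X[tr])
        cov = np.cov(Z.T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-10


class TestLinearOnGroups:
    def test_single_group_is_total_abundance_regression(self, rng):
        X = rng.uniform(size=(40, 5))
        total = X.sum(axis=1)
        F = (2.0 * total + 1.0)[:, None]
        tr, te = training.split_data(40, 0.8, 0)
        labels = np.ones(5, dtype=int)
        assert linear_on_groups(X, F, labels, tr, te) == pytest.approx(1.0)

    def test_linear_truth_with_true_grouping(self):
        v = (1.0, -0.5, -0.1)
        co = benchmark.RegimeCoefficients(a1=v, a2=v, a3=v)
        X, F, truth = benchmark.generate_benchmark(
            benchmark.BenchmarkSpec(n_samples=200, seed=9), co
        )
        tr, te = training.split_data(200, 0.8, 0)
        assert linear_on_groups(X.values, F.values, truth["labels"], tr, te) == pytest.approx(1.0)

    def test_nonlinear_truth_leaves_unexplained_variance(self, small_benchmark):
        X, F, truth = small_benchmark
        tr, te = training.split_data(X.n_samples, 0.8, 0)
        assert linear_on_groups(X.values, F.values, truth["labels"], tr, te) < 0.8


class TestGroupingAgreement:
    def test_identical_up_to_relabelling(self, rng):
        a = rng.integers(1, 4, size=15)
        b = np.array([2, 3, 1])[a - 1]
        assert grouping_agreement(a, b) == 1.0

    def test_partial_agreement(self):
        a = np.array([1, 1, 1, 2])
        b = np.array([1, 1, 2, 2])
        assert grouping_agreement(a, b) == pytest.approx(3 / 4)
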