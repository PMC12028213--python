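"""Fold plans, the four selectors, and the nested evaluation contract."""

import numpy as np
import pytest

from robustrad.classify import (
    _binary_metrics,
    _child_seed,
    make_fold_plan,
    pairwise_auc_scores,
    relieff_weights,
    run_naive_cv,
    run_nested_cv,
    select_auc,
    select_backward,
    select_lasso,
    select_relieff,
)


def _separable_data(rng, n_per_class=12, p_noise=8):
    """Three classes separated along two features, plus pure noise columns."""
    X, y3 = [], []
    means = {"a": (0, 0), "w": (4, 0), "m": (2, 4)}
    for cls, mu in means.items():
        X.append(np.column_stack([
            rng.normal(mu[0], 0.5, n_per_class),
            rng.normal(mu[1], 0.5, n_per_class),
            rng.normal(0, 1, (n_per_class, p_noise)),
        ]))
        y3 += [cls] * n_per_class
    return np.vstack(X), np.array(y3)


class TestFoldPlan:
    def test_fold_sizes_for_43_lesions(self):
        y = np.array([1] * 18 + [0] * 25)
        plan = make_fold_plan(y, k=5, repetitions=3, seed=0)
        for rep in range(3):
            sizes = sorted(np.bincount(plan.assignments[rep]), reverse=True)
            assert sizes == [9, 9, 9, 8, 8]

    def test_same_seed_identical_plan(self):
        y = np.arange(20) % 2
        a = make_fold_plan(y, repetitions=4, seed=9)
        b = make_fold_plan(y, repetitions=4, seed=9)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_each_sample_in_exactly_one_test_fold(self):
        y = np.arange(23) % 2
        plan = make_fold_plan(y, k=5, repetitions=2, seed=1)
        for rep in range(2):
            seen = np.concatenate([plan.split(rep, f)[1] for f in range(5)])
            assert sorted(seen) == list(range(23))

    def test_stratification_keeps_minority_spread(self):
        y = np.array([1] * 10 + [0] * 30)
        plan = make_fold_plan(y, k=5, repetitions=1, seed=0)
        per_fold = [np.sum(y[plan.split(0, f)[1]]) for f in range(5)]
        assert all(c == 2 for c in per_fold)

    def test_tiny_class_warns_and_degrades(self):
        y = np.array([1] * 2 + [0] * 18)
        with pytest.warns(UserWarning, match="smallest class"):
            plan = make_fold_plan(y, k=5, repetitions=1, seed=0)
        assert plan.assignments.shape == (1, 20)


class TestAUCSelector:
    def test_perfectly_ordering_feature_scores_one(self):
        y3 = np.array(["a"] * 5 + ["w"] * 5 + ["m"] * 5)
        X = np.arange(15.0)[:, None]
        sel, scores = select_auc(X, y3)
        assert scores[0] == pytest.approx(1.0)
        assert 0 in sel

    def test_null_feature_dropped(self, rng):
        y3 = np.array(["a", "w", "m"] * 40)
        X = rng.normal(size=(120, 5))
        sel, scores = select_auc(X, y3)
        assert np.all(np.abs(scores - 0.5) < 0.15)
        assert sel.size == 0

    def test_constant_feature_scores_half(self):
        y3 = np.array(["a"] * 5 + ["m"] * 5)
        X = np.ones((10, 1))
        _, scores = select_auc(X, y3)
        assert scores[0] == pytest.approx(0.5)

    def test_threshold_is_strict(self):
        y3 = np.array(["a"] * 4 + ["m"] * 4)
        X = np.arange(8.0)[:, None]
        _, scores = select_auc(X, y3)
        sel, _ = select_auc(X, y3, threshold=float(scores[0]))
        assert sel.size == 0  # score == threshold is not kept

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_auc(np.ones((4, 2)), np.array(["a"] * 4))


class TestReliefF:
    def test_separable_feature_selected(self, rng):
        X, y3 = _separable_data(rng)
        sel, w = select_relieff(X, y3, n_permutations=60, seed=0)
        assert 0 in sel and 1 in sel
        assert w[0] > np.max(w[2:])

    def test_constant_feature_has_zero_weight(self, rng):
        X, y3 = _separable_data(rng)
        X[:, 3] = 5.0
        w = relieff_weights(X, y3)
        assert w[3] == pytest.approx(0.0)

    def test_identical_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="identical"):
            select_relieff(rng.normal(size=(10, 3)), np.zeros(10), n_permutations=30)

    def test_too_few_permutations_rejected(self, rng):
        X, y3 = _separable_data(rng)
        with pytest.raises(ValueError, match="permutations"):
            select_relieff(X, y3, n_permutations=10)

    def test_deterministic_given_seed(self, rng):
        X, y3 = _separable_data(rng)
        s1, w1 = select_relieff(X, y3, n_permutations=40, seed=5)
        s2, w2 = select_relieff(X, y3, n_permutations=40, seed=5)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_allclose(w1, w2)


class TestLasso:
    def test_sparse_recovery(self, rng):
        X, y3 = _separable_data(rng, p_noise=20)
        sel, _ = select_lasso(X, y3, seed=0)
        assert 0 in sel and 1 in sel
        assert sel.size < 12  # most noise columns dropped

    def test_duplicated_informative_feature_keeps_a_copy(self, rng):
        X, y3 = _separable_data(rng, p_noise=4)
        X = np.column_stack([X, X[:, 0]])
        sel, _ = select_lasso(X, y3, seed=0)
        assert 0 in sel or X.shape[1] - 1 in sel

    def test_fallback_returns_single_feature(self, rng):
        """With a near-infinite penalty everything shrinks to zero; the
        fallback still returns exactly one feature."""
        X, y3 = _separable_data(rng, p_noise=2)
        sel, _ = select_lasso(X, y3, seed=0, Cs=np.array([1e-8]))
        assert sel.size == 1


class TestBackward:
    def test_informative_feature_retained(self, rng):
        X, y3 = _separable_data(rng, p_noise=5)
        sel, _ = select_backward(X, y3, seed=0)
        assert 0 in sel and 1 in sel

    def test_identical_features_leave_exactly_one(self, rng):
        y3 = np.array(["a"] * 8 + ["w"] * 8 + ["m"] * 8)
        base = np.r_[rng.normal(0, 0.3, 8), rng.normal(3, 0.3, 8), rng.normal(6, 0.3, 8)]
        X = np.tile(base[:, None], (1, 4))
        sel, _ = select_backward(X, y3, seed=0)
        assert sel.size == 1

    def test_single_feature_returned_unchanged(self, rng):
        X = rng.normal(size=(12, 1))
        y3 = np.array(["a", "m"] * 6)
        sel, _ = select_backward(X, y3, seed=0)
        np.testing.assert_array_equal(sel, [0])

    def test_prescreen_caps_start_size(self, rng):
        X, y3 = _separable_data(rng, p_noise=40)
        sel, _ = select_backward(X, y3, seed=0, max_start_features=10)
        assert sel.size <= 10


class TestNestedCV:
    def test_metrics_consistent_with_confusion_matrix(self, rng):
        y = rng.integers(0, 2, 50)
        pred = rng.integers(0, 2, 50)
        acc, sens, spec = _binary_metrics(y, pred)
        tp = np.sum((y == 1) & (pred == 1))
        tn = np.sum((y == 0) & (pred == 0))
        assert acc == pytest.approx((tp + tn) / 50)
        assert sens == pytest.approx(tp / np.sum(y == 1))
        assert spec == pytest.approx(tn / np.sum(y == 0))

    def test_selection_uses_training_rows_only(self, rng):
        """Leakage check: scrambling the held-out rows must not change the
        per-fold selected feature set."""
        X, y3 = _separable_data(rng)
        y2 = (y3 == "m").astype(int)
        plan = make_fold_plan(y2, k=5, repetitions=1, seed=2)
        train, test = plan.split(0, 0)
        seed = _child_seed(plan.seed, 0, 0)
        sel_before, _ = select_auc(X[train], y3[train])
        X_scrambled = X.copy()
        X_scrambled[test] = rng.normal(size=(test.size, X.shape[1]))
        sel_after, _ = select_auc(X_scrambled[train], y3[train])
        np.testing.assert_array_equal(sel_before, sel_after)

    def test_separable_data_high_accuracy(self, rng):
        X, y3 = _separable_data(rng)
        y2 = (y3 == "m").astype(int)
        plan = make_fold_plan(y2, k=5, repetitions=2, seed=3)
        res = run_nested_cv(X, y2, y3, plan, selectors=("auc",),
                            classifiers=("lda", "knn"), seed=3)
        acc = res.performance.query("metric == 'accuracy'")["mean"]
        assert (acc > 0.9).all()

    def test_all_pairs_share_identical_folds(self, rng):
        """The shared-folds contract: the fold plan object is the single
        source of splits, so test indices agree across pairs by construction;
        verify the split is a deterministic function of (rep, fold)."""
        y = np.arange(30) % 2
        plan = make_fold_plan(y, k=5, repetitions=2, seed=4)
        for rep in range(2):
            for fold in range(5):
                a = plan.split(rep, fold)[1]
                b = plan.split(rep, fold)[1]
                np.testing.assert_array_equal(a, b)

    def test_selection_frequency_bounded_and_recorded(self, rng):
        X, y3 = _separable_data(rng)
        y2 = (y3 == "m").astype(int)
        plan = make_fold_plan(y2, k=5, repetitions=2, seed=5)
        res = run_nested_cv(X, y2, y3, plan, selectors=("auc",),
                            classifiers=("lda",), seed=5)
        freq = res.selection_frequency["frequency"]
        assert ((freq > 0) & (freq <= 1)).all()
        # the two informative features are selected in >= 80% of iterations
        top = res.selection_frequency.query("frequency >= 0.8")["feature"]
        assert {"f0", "f1"} <= set(top)

    def test_naive_protocol_runs_with_full_data_selection(self, rng):
        X, y3 = _separable_data(rng)
        y2 = (y3 == "m").astype(int)
        plan = make_fold_plan(y2, k=5, repetitions=1, seed=6)
        res = run_naive_cv(X, y2, y3, plan, selectors=("auc",), classifiers=("lda",))
        assert len(res.records) == 5
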