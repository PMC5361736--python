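import numpy as np
import pytest

from knnmdr.engine import (
    ConfusionCounts,
    CVPlan,
    KnnConfig,
    balanced_accuracy,
    confusion_counts,
    cross_validated_ba,
    cv_neighbors,
    knn_cv_ba_batch,
    knn_predict,
    make_cv_plan,
    mdr_cv_ba_batch,
    mdr_predict,
)
from knnmdr.windowing import window_squared_distances


def brute_force_knn(d2, train_idx, test_idx, is_case, k, tie_rule="nearest_neighbor_breaks"):
    """Oracle: python sort of (distance, index) pairs per test point."""
    preds = []
    for t in test_idx:
        ranked = sorted((d2[t, j], j) for j in train_idx)[:k]
        votes = sum(is_case[j] for _, j in ranked)
        if votes * 2 > k:
            preds.append(True)
        elif votes * 2 < k:
            preds.append(False)
        elif tie_rule == "nearest_neighbor_breaks":
            preds.append(bool(is_case[ranked[0][1]]))
        else:
            preds.append(tie_rule == "case_wins")
    return np.array(preds)


class TestKnnPredict:
    def _toy(self):
        d2 = np.array(
            [
                [0.0, 1.0, 2.0, 3.0],
                [1.0, 0.0, 1.5, 2.5],
                [2.0, 1.5, 0.0, 1.0],
                [3.0, 2.5, 1.0, 0.0],
            ]
        )
        return d2

    def test_k1_copies_nearest(self):
        d2 = self._toy()
        is_case = np.array([True, False, False, True])
        pred = knn_predict(d2, np.array([0, 1, 2]), np.array([3]), is_case, KnnConfig(k=1))
        assert pred.tolist() == [False]  # nearest trainee is 2 (control)

    def test_k3_majority(self):
        d2 = self._toy()
        is_case = np.array([True, True, False, False])
        pred = knn_predict(d2, np.array([0, 1, 2]), np.array([3]), is_case, KnnConfig(k=3))
        assert pred.tolist() == [True]  # case, case, control -> case

    def test_tie_broken_by_nearest(self):
        d2 = np.array(
            [[0.0, 1.0, 2.0], [1.0, 0.0, 9.0], [2.0, 9.0, 0.0]]
        )
        is_case = np.array([False, True, False])
        # test 0, K=2: neighbors 1 (case, d=1) and 2 (control, d=2) -> tie -> nearest (case)
        pred = knn_predict(d2, np.array([1, 2]), np.array([0]), is_case, KnnConfig(k=2))
        assert pred.tolist() == [True]
        pred = knn_predict(
            d2, np.array([1, 2]), np.array([0]), is_case, KnnConfig(k=2, tie_rule="control_wins")
        )
        assert pred.tolist() == [False]

    def test_matches_brute_force(self, random_genotypes):
        vals = random_genotypes(30, 12, seed=5)
        d2 = window_squared_distances(vals, (0, 12))
        r = np.random.default_rng(0)
        is_case = r.random(30) < 0.5
        test_idx = np.sort(r.choice(30, size=8, replace=False))
        train_idx = np.setdiff1d(np.arange(30), test_idx)
        pred = knn_predict(d2, train_idx, test_idx, is_case, KnnConfig(k=5))
        oracle = brute_force_knn(d2, train_idx, test_idx, is_case, 5)
        np.testing.assert_array_equal(pred, oracle)

    def test_k_too_large(self):
        d2 = self._toy()
        with pytest.raises(ValueError, match="K"):
            knn_predict(d2, np.array([0, 1]), np.array([2]), np.array([1, 0, 1], bool), KnnConfig(k=3))

    def test_overlapping_sets_rejected(self):
        d2 = self._toy()
        with pytest.raises(ValueError, match="disjoint"):
            knn_predict(d2, np.array([0, 1]), np.array([1, 2]), np.zeros(4, bool), KnnConfig(k=1))

    def test_empty_test_set(self):
        d2 = self._toy()
        pred = knn_predict(d2, np.array([0, 1, 2]), np.array([], int), np.array([1, 0, 1, 0], bool), KnnConfig(k=1))
        assert pred.size == 0

    def test_permutation_equivariance(self, random_genotypes):
        vals = random_genotypes(20, 6, seed=9)
        d2 = window_squared_distances(vals, (0, 6))
        r = np.random.default_rng(3)
        is_case = r.random(20) < 0.5
        # perturb distances so no exact ties cross the reorder
        d2 = d2 + r.random(d2.shape) * 1e-9
        d2 = (d2 + d2.T) / 2
        np.fill_diagonal(d2, 0)
        perm = r.permutation(20)
        d2p = d2[np.ix_(perm, perm)]
        inv = np.argsort(perm)
        test = np.array([0, 5, 11])
        train = np.setdiff1d(np.arange(20), test)
        pred = knn_predict(d2, train, test, is_case, KnnConfig(k=5))
        test_p = np.sort(inv[test])
        train_p = np.setdiff1d(np.arange(20), test_p)
        pred_p = knn_predict(d2p, train_p, test_p, is_case[perm], KnnConfig(k=5))
        order = np.argsort(inv[test])
        np.testing.assert_array_equal(pred[order], pred_p)


class TestMdrPredict:
    def test_pure_cell_majority(self):
        vals = np.array([[0], [0], [1], [1], [2], [2]], dtype=np.int8)
        is_case = np.array([True, True, False, False, True, False])
        pred = mdr_predict(vals, [0], np.arange(5), np.array([5]), is_case)
        # training cell {2}: 1 case, 0 controls; ratio 1:0 > 3:2 -> case
        assert pred.tolist() == [1]

    def test_unseen_cell_unclassifiable(self):
        vals = np.array([[0], [0], [1], [2]], dtype=np.int8)
        is_case = np.array([True, False, True, False])
        pred = mdr_predict(vals, [0], np.array([0, 1, 2]), np.array([3]), is_case)
        assert pred.tolist() == [-1]

    def test_two_marker_cells_match_tally_oracle(self, random_genotypes):
        vals = random_genotypes(12, 2, seed=21)
        is_case = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1, 0], dtype=bool)
        train = np.arange(10)
        test = np.array([10, 11])
        pred = mdr_predict(vals, [0, 1], train, test, is_case)
        # oracle: explicit per-cell tallies
        tallies = {}
        for i in train:
            cell = (vals[i, 0], vals[i, 1])
            cases, ctrls = tallies.get(cell, (0, 0))
            tallies[cell] = (cases + is_case[i], ctrls + (not is_case[i]))
        n_cases = int(is_case[train].sum())
        n_ctrls = len(train) - n_cases
        for t, p in zip(test, pred):
            cell = (vals[t, 0], vals[t, 1])
            if cell not in tallies:
                assert p == -1
            else:
                cases, ctrls = tallies[cell]
                assert p == int(cases * n_ctrls > ctrls * n_cases)

    def test_equal_ratio_is_low_risk(self):
        vals = np.array([[0]] * 5 + [[1]], dtype=np.int8)
        is_case = np.array([True, False, True, False, True, False])
        pred = mdr_predict(vals, [0], np.arange(4), np.array([4]), is_case)
        assert pred.tolist() == [0]  # 2:2 cell equals the 2:2 base ratio -> control

    def test_all_unique_cells_classify_nothing(self):
        # the failure mode the KNN vote removes: singleton training cells
        # leave every *new* genotype unclassifiable
        vals = np.arange(27, dtype=np.int64)
        vals = np.stack([vals // 9 % 3, vals // 3 % 3, vals % 3], axis=1).astype(np.int8)
        train = np.arange(13)
        test = np.arange(13, 27)
        is_case = np.tile([True, False], 14)[:27]
        pred = mdr_predict(vals, [0, 1, 2], train, test, is_case)
        assert np.all(pred == -1)


class TestBalancedAccuracy:
    def test_perfect(self):
        assert balanced_accuracy(ConfusionCounts(5, 0, 5, 0)) == 1.0

    def test_arithmetic(self):
        assert balanced_accuracy(ConfusionCounts(3, 1, 2, 2)) == pytest.approx(0.625)

    def test_always_case_on_balanced_data(self):
        assert balanced_accuracy(ConfusionCounts(4, 0, 0, 4)) == pytest.approx(0.5)

    def test_degenerate_class_rate_half(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            ba = balanced_accuracy(ConfusionCounts(0, 0, 3, 1))
        assert ba == pytest.approx(0.5 * (0.5 + 0.75))

    def test_confusion_counts_excludes_unclassified(self):
        is_case = np.array([True, True, False])
        pred = np.array([1, -1, 0], dtype=np.int8)
        c = confusion_counts(is_case, pred)
        assert (c.tp, c.fn, c.tn, c.fp, c.unclassified) == (1, 0, 1, 0, 1)


class TestCVPlan:
    def test_stratification_within_one(self):
        is_case = np.zeros(95, dtype=bool)
        is_case[:40] = True
        plan = make_cv_plan(is_case, n_folds=10, seed=7)
        for f in range(10):
            fold_cases = int(is_case[plan.fold_indices(f)].sum())
            assert fold_cases in (3, 4)  # 40 cases / 10 folds

    def test_folds_partition(self):
        plan = make_cv_plan(np.tile([True, False], 25), n_folds=10, seed=1)
        counted = np.concatenate([plan.fold_indices(f) for f in range(10)])
        assert sorted(counted.tolist()) == list(range(50))

    def test_empty_fold_rejected(self):
        with pytest.raises(ValueError):
            CVPlan(np.zeros(5, dtype=int), n_folds=2, stratified=False, seed=0)


class TestCrossValidatedBA:
    def test_truth_stub_scores_one(self):
        is_case = np.tile([True, False], 15)
        plan = make_cv_plan(is_case, n_folds=5, seed=0)
        stub = lambda train_idx, test_idx: is_case[test_idx].astype(np.int8)
        assert cross_validated_ba(is_case, plan, method=stub) == 1.0

    def test_null_data_near_half(self, random_genotypes):
        bas = []
        for seed in range(20):
            vals = random_genotypes(100, 20, seed=seed)
            r = np.random.default_rng(seed + 1000)
            is_case = np.zeros(100, dtype=bool)
            is_case[r.choice(100, 50, replace=False)] = True
            d2 = window_squared_distances(vals, (0, 20))
            plan = make_cv_plan(is_case, n_folds=10, seed=seed)
            bas.append(
                cross_validated_ba(is_case, plan, d2=d2, knn_cfg=KnnConfig(k=10))
            )
        assert abs(np.mean(bas) - 0.5) < 0.05

    def test_separable_window_scores_high(self):
        # genotypes at one window perfectly separate the statuses
        is_case = np.tile([True, False], 20)
        separating = np.where(is_case[:, None], 2, 0).astype(np.int8)
        noise = np.tile([0, 1], 20)[:, None].astype(np.int8)
        vals = np.hstack([separating, noise])
        d2 = window_squared_distances(vals, (0, 1))
        plan = make_cv_plan(is_case, n_folds=10, seed=0)
        ba = cross_validated_ba(is_case, plan, d2=d2, knn_cfg=KnnConfig(k=5))
        assert ba > 0.95

    def test_batch_path_equals_per_fold_path(self, random_genotypes):
        vals = random_genotypes(60, 15, seed=3)
        r = np.random.default_rng(17)
        is_case = r.random(60) < 0.5
        d2 = window_squared_distances(vals, (0, 15))
        plan = make_cv_plan(is_case, n_folds=6, seed=2)
        cfg = KnnConfig(k=7)
        slow = cross_validated_ba(is_case, plan, d2=d2, knn_cfg=cfg)
        fast = knn_cv_ba_batch(d2, plan, is_case[None, :], cfg)[0]
        assert fast == pytest.approx(slow)

    def test_mdr_batch_equals_per_fold_path(self, random_genotypes):
        vals = random_genotypes(60, 4, seed=4)
        r = np.random.default_rng(23)
        is_case = r.random(60) < 0.5
        plan = make_cv_plan(is_case, n_folds=5, seed=2)
        slow = cross_validated_ba(is_case, plan, method="mdr", values=vals, marker_idx=[1, 3])
        fast = mdr_cv_ba_batch(vals, [1, 3], plan, is_case[None, :])[0]
        assert fast == pytest.approx(slow)

    def test_permuted_phenotypes_centre_on_half(self, random_genotypes):
        vals = random_genotypes(80, 10, seed=6)
        d2 = window_squared_distances(vals, (0, 10))
        is_case = np.tile([True, False], 40)
        plan = make_cv_plan(is_case, n_folds=10, seed=0)
        r = np.random.default_rng(99)
        Y = np.stack([r.permutation(is_case) for _ in range(200)])
        bas = knn_cv_ba_batch(d2, plan, Y, KnnConfig(k=5))
        se = bas.std(ddof=1) / np.sqrt(len(bas))
        assert abs(bas.mean() - 0.5) < 2 * se + 0.01

    def test_cv_neighbors_never_own_fold(self, random_genotypes):
        vals = random_genotypes(40, 8, seed=8)
        d2 = window_squared_distances(vals, (0, 8))
        plan = make_cv_plan(np.tile([True, False], 20), n_folds=4, seed=5)
        nb = cv_neighbors(d2, plan, 6)
        folds = np.asarray(plan.fold_ids)
        for i in range(40):
            assert np.all(folds[nb[i]] != folds[i])
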