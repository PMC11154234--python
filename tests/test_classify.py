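"""Classifier stack tests: LOO bookkeeping, wrapper selection, anomaly scan."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from cardioresp import classify
from cardioresp.classify import (CLASS_TASKS, FAMILIES, FEATURES,
                                 SubspaceDiscriminantEnsemble, accuracy,
                                 anomaly_scan, build_task_data, loo_evaluate,
                                 wrapper_select)


def ratio_frame(x_by_stage, stages=("5", "1A"), n_features=9):
    """Ratio table from per-stage feature matrices (n_subjects x features)."""
    rows = {}
    n = next(iter(x_by_stage.values())).shape[0]
    for sid in range(1, n + 1):
        for stage in stages:
            rows[(sid, stage)] = dict(zip(FEATURES[:n_features],
                                          x_by_stage[stage][sid - 1]))
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index,
                                         names=["subject", "stage"])
    return df


def gaussian_task(rng, n=14, d_prime=3.0, n_features=9, informative=0):
    """Two-stage task where one feature separates the stages at d'."""
    a = rng.normal(0.0, 1.0, size=(n, n_features))
    b = rng.normal(0.0, 1.0, size=(n, n_features))
    b[:, informative] += d_prime
    return ratio_frame({"5": a, "1A": b}, n_features=n_features)


class TestAccuracy:
    def test_all_correct(self):
        assert accuracy(np.ones(10, dtype=bool)) == 100.0

    def test_zero_cases_rejected(self):
        with pytest.raises(ValueError):
            accuracy(np.empty(0, dtype=bool))

    def test_fractional(self):
        assert accuracy([True, True, False, True]) == pytest.approx(75.0)


class TestBuildTaskData:
    def test_two_cases_per_subject(self):
        rng = np.random.default_rng(0)
        ratios = gaussian_task(rng, n=10)
        x, y, s = build_task_data(ratios, CLASS_TASKS["C.5-1A"])
        assert x.shape == (20, 9)
        assert all(np.sum(s == sid) == 2 for sid in np.unique(s))
        assert set(y) == {0, 1}

    def test_subject_missing_stage_excluded(self):
        rng = np.random.default_rng(1)
        ratios = gaussian_task(rng, n=10)
        ratios = ratios.drop(index=(3, "1A"))
        x, y, s = build_task_data(ratios, CLASS_TASKS["C.5-1A"])
        assert 3 not in s and x.shape[0] == 18

    def test_three_class_task_grouping(self):
        rng = np.random.default_rng(2)
        rows = {}
        for sid in range(1, 9):
            for stage in ("3D", "5", "3A", "1A"):
                rows[(sid, stage)] = dict(
                    zip(FEATURES, rng.normal(size=9)))
        ratios = pd.DataFrame.from_dict(rows, orient="index")
        ratios.index = pd.MultiIndex.from_tuples(ratios.index,
                                                 names=["subject", "stage"])
        x, y, s = build_task_data(ratios, CLASS_TASKS["C.3DA-5-1A"])
        assert x.shape[0] == 8 * 4
        # 3D and 3A share class 0
        assert np.sum(y == 0) == 16


class TestLooEvaluate:
    def test_separable_task_perfect_for_every_family(self):
        rng = np.random.default_rng(3)
        ratios = gaussian_task(rng, n=14, d_prime=12.0)
        x, y, s = build_task_data(ratios, CLASS_TASKS["C.5-1A"])
        for fam in FAMILIES:
            res = loo_evaluate(x, y, s, fam, [0])
            assert res.accuracy == 100.0, fam

    def test_permutation_null_accuracy_near_chance(self):
        # label permutation respecting the task structure (one row per class
        # per subject: swap each subject's pair or not); LOO training folds
        # then stay balanced and the null accuracy is 50%
        rng = np.random.default_rng(4)
        accs = []
        for _ in range(200):
            ratios = gaussian_task(rng, n=12, d_prime=0.0, n_features=1)
            x, y, s = build_task_data(ratios, CLASS_TASKS["C.5-1A"],
                                      features=FEATURES[:1])
            y = y.copy()
            for sid in np.unique(s):
                if rng.random() < 0.5:
                    m = s == sid
                    y[m] = 1 - y[m]
            accs.append(loo_evaluate(x, y, s, "LDA", [0]).accuracy)
        assert abs(np.mean(accs) - 50.0) <= 5.0

    def test_single_feature_lda_tracks_bayes_rate(self):
        # d' = 1 two-class Gaussian: Bayes accuracy = Phi(d'/2) ~ 69%
        rng = np.random.default_rng(5)
        accs = [loo_evaluate(*build_task_data(
            gaussian_task(rng, n=24, d_prime=1.0, n_features=1),
            CLASS_TASKS["C.5-1A"], features=FEATURES[:1]),
            "LDA", [0]).accuracy for _ in range(30)]
        expected = 100 * norm.cdf(0.5)
        assert abs(np.mean(accs) - expected) <= 10.0

    def test_no_leakage_from_held_out_labels(self):
        # flipping one subject's labels must not change the predictions for
        # any other subject (the held-out subject never trains)
        rng = np.random.default_rng(6)
        ratios = gaussian_task(rng, n=12, d_prime=1.0)
        x, y, s = build_task_data(ratios, CLASS_TASKS["C.5-1A"])
        base = loo_evaluate(x, y, s, "LDA", [0, 1])
        y2 = y.copy()
        flip = s == 5
        y2[flip] = 1 - y2[flip]
        res = loo_evaluate(x, y2, s, "LDA", [0, 1])
        others = s != 5
        assert np.array_equal(base.correct[others], res.correct[others])

    def test_z_scoring_makes_scale_irrelevant_for_knn(self):
        rng = np.random.default_rng(7)
        ratios = gaussian_task(rng, n=12, d_prime=2.0)
        x, y, s = build_task_data(ratios, CLASS_TASKS["C.5-1A"])
        a = loo_evaluate(x, y, s, "KNN", [0, 1])
        x_scaled = x.copy()
        x_scaled[:, 1] *= 1e4
        b = loo_evaluate(x_scaled, y, s, "KNN", [0, 1])
        assert a.accuracy == b.accuracy


class TestKnnFastPath:
    def test_matches_sklearn_cosine_knn(self):
        from sklearn.neighbors import KNeighborsClassifier
        from cardioresp.classify import _knn_cosine_predict
        rng = np.random.default_rng(20)
        for _ in range(20):
            xt = rng.normal(size=(54, 4))
            yt = rng.integers(0, 2, 54)
            xh = rng.normal(size=(6, 4))
            ref = KNeighborsClassifier(n_neighbors=10, metric="cosine",
                                       algorithm="brute").fit(xt, yt)
            assert np.array_equal(_knn_cosine_predict(xt, yt, xh),
                                  ref.predict(xh))


class TestDec:
    def test_matches_lda_in_separable_case(self):
        rng = np.random.default_rng(8)
        x = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(6, 1, (30, 4))])
        y = np.repeat([0, 1], 30)
        dec = SubspaceDiscriminantEnsemble(random_state=0).fit(x, y)
        assert np.array_equal(dec.predict(x), y)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(40, 6))
        y = rng.integers(0, 2, 40)
        p1 = SubspaceDiscriminantEnsemble(random_state=3).fit(x, y).predict(x)
        p2 = SubspaceDiscriminantEnsemble(random_state=3).fit(x, y).predict(x)
        assert np.array_equal(p1, p2)


class TestWrapperSelect:
    def test_perfect_feature_selected_first(self):
        rng = np.random.default_rng(10)
        ratios = gaussian_task(rng, n=14, d_prime=12.0, informative=4)
        x, y, s = build_task_data(ratios, CLASS_TASKS["C.5-1A"])
        wr = wrapper_select(x, y, s, "LDA", seed=0)
        assert wr.order[0] == 4
        assert wr.curve[0] == 100.0

    def test_step_two_matches_exhaustive_pair_search(self):
        rng = np.random.default_rng(11)
        for trial in range(5):
            ratios = gaussian_task(rng, n=10, d_prime=1.5, n_features=5)
            x, y, s = build_task_data(ratios, CLASS_TASKS["C.5-1A"],
                                      features=FEATURES[:5])
            wr = wrapper_select(x, y, s, "LDA", seed=trial)
            f1 = wr.order[0]
            best_pair = max(
                (loo_evaluate(x, y, s, "LDA", [f1, f2]).accuracy
                 for f2 in range(5) if f2 != f1))
            assert wr.curve[1] == pytest.approx(best_pair)

    def test_duplicate_features_tie_resolved_reproducibly(self):
        rng = np.random.default_rng(12)
        ratios = gaussian_task(rng, n=10, d_prime=8.0, n_features=2)
        # make feature 1 an exact duplicate of feature 0
        ratios[FEATURES[1]] = ratios[FEATURES[0]]
        x, y, s = build_task_data(ratios, CLASS_TASKS["C.5-1A"],
                                  features=FEATURES[:2])
        a = wrapper_select(x, y, s, "LDA", seed=5)
        b = wrapper_select(x, y, s, "LDA", seed=5)
        assert a.order == b.order
        assert a.curve == b.curve
        assert a.curve[0] == a.curve[1]  # the duplicate adds nothing

    def test_full_curve_has_nine_points(self):
        rng = np.random.default_rng(13)
        ratios = gaussian_task(rng, n=10, d_prime=1.0)
        x, y, s = build_task_data(ratios, CLASS_TASKS["C.5-1A"])
        wr = wrapper_select(x, y, s, "KNN", seed=0)
        assert len(wr.curve) == 9 and len(wr.order) == 9
        assert sorted(wr.order) == list(range(9))


class TestAnomalyScan:
    def _grid(self, accs, correct_by_cell, subjects):
        cells = [classify.LooResult(accuracy=a, correct=c, subjects=subjects)
                 for a, c in zip(accs, correct_by_cell)]
        wr = classify.WrapperResult(family="LDA", order=[], curve=list(accs),
                                    cells=cells)
        return {"LDA": wr}

    def test_strictly_above_threshold_counts(self):
        subjects = np.repeat(np.arange(1, 6), 2)
        correct = np.ones(10, dtype=bool)
        correct[0] = False  # subject 1 misclassified once
        grid = self._grid([70.0, 70.1], [np.ones(10, dtype=bool), correct],
                          subjects)
        rep = anomaly_scan(grid, threshold=70.0, flag_count=0)
        assert rep.n_qualifying == 1      # the 70.0 cell is excluded
        assert rep.counts.get(1, 0) == 1

    def test_counts_accumulate_across_task_pairs(self):
        subjects = np.repeat(np.arange(1, 4), 2)
        bad = np.ones(6, dtype=bool)
        bad[4:] = False  # subject 3 misses both cases
        g1 = self._grid([90.0], [bad], subjects)
        g2 = self._grid([95.0], [bad], subjects)
        rep = anomaly_scan([g1, g2], flag_count=3)
        assert rep.counts[3] == 4
        assert rep.flagged == [3]

    def test_no_qualifying_cells(self):
        subjects = np.repeat(np.arange(1, 4), 2)
        grid = self._grid([50.0], [np.ones(6, dtype=bool)], subjects)
        rep = anomaly_scan(grid)
        assert rep.n_qualifying == 0 and rep.counts.empty
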