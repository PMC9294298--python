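import numpy as np
import pytest

from capfreq import (
    ClassifierConfig,
    FeatureMatrix,
    SubjectMeta,
    build_feature_matrix,
    classification_metrics,
    consensus_features,
    f_score,
    loo_cv,
    lopo_cv,
    match_controls,
    state_feature_map,
)
from capfreq.cap_states import StateSequence
from capfreq.classification import random_pairs, rank_features
from capfreq.signal_band import ROITimeSeries

SMALL_GRID = (2, 4, 8, 16)


def _gaussian_problem(rng, n_pairs=20, n_feat=40, delta=0.0):
    """Balanced two-class features; first 5 features carry the group shift."""
    n = 2 * n_pairs
    X = rng.standard_normal((n, n_feat))
    y = np.r_[np.ones(n_pairs, int), np.zeros(n_pairs, int)]
    X[y == 1, :5] += delta
    fm = FeatureMatrix(X, [f"f{i}" for i in range(n_feat)],
                       [f"s{i}" for i in range(n)])
    pairs = list(zip(range(n_pairs), range(n_pairs, n)))
    return fm, y, pairs


class TestFeatureConstruction:
    def test_state_map_averages_member_frames(self, rng):
        data = rng.standard_normal((12, 7))
        labels = np.tile([1, 2, 3], 4)
        ts = ROITimeSeries("s", data, tr=2.0)
        seq = StateSequence("s", labels, tr=2.0, n_states=3)
        m = state_feature_map(ts, seq, 3)
        for k in range(1, 4):
            np.testing.assert_allclose(m[k - 1], data[labels == k].mean(axis=0))

    def test_missing_state_raises(self, rng):
        ts = ROITimeSeries("s", rng.standard_normal((6, 4)), tr=2.0)
        seq = StateSequence("s", np.array([1, 1, 2, 2, 1, 2]), tr=2.0, n_states=3)
        with pytest.raises(ValueError, match="state 3"):
            state_feature_map(ts, seq, 3)

    def test_single_band_dimension_is_k_times_r(self, rng):
        maps = {f"s{i}": [("slow4", rng.standard_normal((6, 408)))] for i in range(3)}
        fm = build_feature_matrix(maps)
        assert fm.n_features == 2448

    def test_two_band_concatenation_doubles_dimension(self, rng):
        maps = {
            "s0": [("slow5", rng.standard_normal((6, 408))),
                   ("slow4", rng.standard_normal((6, 408)))],
        }
        assert build_feature_matrix(maps).n_features == 4896

    def test_constant_state_frames_reproduced_in_block(self, rng):
        v = rng.standard_normal(5)
        data = np.vstack([v, v, rng.standard_normal((2, 5))])
        labels = np.array([1, 1, 2, 2])
        ts = ROITimeSeries("s", data, tr=2.0)
        seq = StateSequence("s", labels, tr=2.0, n_states=2)
        m = state_feature_map(ts, seq, 2)
        np.testing.assert_allclose(m[0], v)


class TestFScore:
    def test_hand_example(self):
        X = np.array([[2.0], [4.0], [0.0], [2.0]])
        y = np.array([1, 1, 0, 0])
        assert f_score(X, y)[0] == pytest.approx(0.5)

    def test_identical_distributions_zero(self):
        X = np.array([[1.0], [2.0], [1.0], [2.0]])
        y = np.array([1, 1, 0, 0])
        assert f_score(X, y)[0] == pytest.approx(0.0)

    def test_scale_invariance(self, rng):
        X = rng.standard_normal((30, 8))
        y = rng.integers(0, 2, 30)
        while len(np.unique(y)) < 2 or min(np.sum(y == 0), np.sum(y == 1)) < 2:
            y = rng.integers(0, 2, 30)
        np.testing.assert_allclose(f_score(X, y), f_score(X * 13.7, y))

    def test_matches_direct_formula_oracle(self, rng):
        X = rng.standard_normal((24, 10))
        y = np.r_[np.ones(12, int), np.zeros(12, int)]
        scores = f_score(X, y)
        for j in range(10):
            pos, neg = X[y == 1, j], X[y == 0, j]
            xb = X[:, j].mean()
            expected = ((pos.mean() - xb) ** 2 + (neg.mean() - xb) ** 2) / (
                pos.var(ddof=1) + neg.var(ddof=1)
            )
            assert scores[j] == pytest.approx(expected, abs=1e-12)

    def test_undefined_scores_ranked_last(self):
        X = np.column_stack([np.r_[np.ones(4), np.zeros(4)], np.ones(8)])
        y = np.r_[np.ones(4, int), np.zeros(4, int)]
        order = rank_features(f_score(X, y))
        assert order.tolist() == [0, 1]


class TestCrossValidation:
    def test_separable_problem_perfect(self, rng):
        fm, y, pairs = _gaussian_problem(rng, n_pairs=12, delta=6.0)
        cfg = ClassifierConfig(feature_grid=SMALL_GRID, seed=0)
        rep = lopo_cv(fm, y, pairs, cfg)
        assert rep.acc == 1.0 and rep.auc == 1.0

    def test_lopo_equals_loo_on_separable_data(self, rng):
        fm, y, pairs = _gaussian_problem(rng, n_pairs=10, delta=6.0)
        cfg = ClassifierConfig(feature_grid=SMALL_GRID, seed=0)
        assert lopo_cv(fm, y, pairs, cfg).acc == loo_cv(fm, y, cfg).acc == 1.0

    def test_chance_level_on_permuted_labels(self, rng):
        fm, y, pairs = _gaussian_problem(rng, n_pairs=100, n_feat=50, delta=0.0)
        cfg = ClassifierConfig(feature_grid=(10, 20, 30), seed=0)
        rep = lopo_cv(fm, y, pairs, cfg)
        assert 0.4 <= rep.acc <= 0.6

    def test_four_pair_toy_matches_manual_trace(self):
        # 1-D problem small enough to execute LOPO by hand: class means are
        # +/-2; every held-out pair is classified by the margin of the other 3
        X = np.array([[2.1], [1.9], [2.2], [1.8], [-2.1], [-1.9], [-2.2], [-1.8]])
        y = np.r_[np.ones(4, int), np.zeros(4, int)]
        fm = FeatureMatrix(X, ["f0"], [f"s{i}" for i in range(8)])
        pairs = [(0, 4), (1, 5), (2, 6), (3, 7)]
        rep = lopo_cv(fm, y, pairs, ClassifierConfig(feature_grid=(1,)))
        assert rep.acc == 1.0 and rep.chosen_feature_number == 1

    def test_smallest_grid_step_wins_ties(self, rng):
        fm, y, pairs = _gaussian_problem(rng, n_pairs=10, delta=6.0)
        rep = lopo_cv(fm, y, pairs, ClassifierConfig(feature_grid=(4, 8, 12)))
        accs = rep.accuracy_by_n_features
        best = max(accs.values())
        assert rep.chosen_feature_number == min(
            n for n, a in accs.items() if a == best
        )

    def test_duplicate_subject_in_pairs_rejected(self, rng):
        fm, y, _ = _gaussian_problem(rng, n_pairs=3)
        with pytest.raises(ValueError, match="more than one pair"):
            lopo_cv(fm, y, [(0, 3), (0, 4), (2, 5)],
                    ClassifierConfig(feature_grid=(2,)))

    def test_full_data_selection_inflates_null_accuracy(self, rng):
        # negative control: ranking features on ALL subjects before CV leaks
        fm, y, pairs = _gaussian_problem(rng, n_pairs=30, n_feat=400, delta=0.0)
        cfg = ClassifierConfig(feature_grid=(10,))
        honest = lopo_cv(fm, y, pairs, cfg).acc
        leaked_cols = rank_features(f_score(fm.X, y))[:10]
        leaked_fm = FeatureMatrix(
            fm.X[:, leaked_cols], [fm.feature_names[c] for c in leaked_cols],
            fm.subject_ids,
        )
        leaked = lopo_cv(leaked_fm, y, pairs, cfg).acc
        assert leaked - honest >= 0.1


class TestMetricsAndConsensus:
    def test_perfect_predictions(self):
        rep = classification_metrics([1, 0, 1, 0], [1, 0, 1, 0], [2.0, -2, 1, -1])
        assert rep.acc == rep.se == rep.sp == rep.auc == 1.0

    def test_confusion_matrix_hand_example(self):
        truth = [1, 1, 1, 1, 0, 0, 0, 0]
        pred = [1, 1, 1, 0, 1, 1, 0, 0]
        dv = [1.0, 2, 3, -1, 0.5, 0.4, -2, -3]
        rep = classification_metrics(truth, pred, dv)
        assert rep.se == 0.75 and rep.sp == 0.5 and rep.acc == 0.625

    def test_auc_matches_pairwise_oracle(self, rng):
        truth = rng.integers(0, 2, 50)
        while len(np.unique(truth)) < 2:
            truth = rng.integers(0, 2, 50)
        dv = rng.standard_normal(50)
        rep = classification_metrics(truth, (dv > 0).astype(int), dv)
        pos, neg = dv[truth == 1], dv[truth == 0]
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        )
        assert rep.auc == pytest.approx(wins / (pos.size * neg.size), abs=1e-8)

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            classification_metrics([1, 1], [1, 0], [1.0, -1.0])

    def test_consensus_always_and_boundary(self):
        # feature 0 selected in every iteration, feature 1 in 79% of them
        n_iter = 100
        sels = [
            [np.array([0] + ([1] if i < 79 else [])) for i in range(n_iter)]
            for _ in range(5)
        ]
        cons = consensus_features(sels, n_features=3)
        assert cons.tolist() == [0]

    def test_consensus_matches_counting_oracle(self, rng):
        n_rep, n_iter, n_feat = 6, 30, 12
        sels = [
            [rng.choice(n_feat, size=4, replace=False) for _ in range(n_iter)]
            for _ in range(n_rep)
        ]
        cons = consensus_features(sels, n_feat, 0.5, 0.5)
        # direct two-pass tally
        flagged = []
        for rep in sels:
            counts = np.zeros(n_feat)
            for s in rep:
                counts[s] += 1
            flagged.append(counts / n_iter >= 0.5)
        expected = np.flatnonzero(np.mean(flagged, axis=0) >= 0.5)
        np.testing.assert_array_equal(cons, expected)


class TestMatching:
    @staticmethod
    def _meta(group, ages, sexes):
        return [
            SubjectMeta(f"{group.lower()}{i}", group, a, s, 0.08)
            for i, (a, s) in enumerate(zip(ages, sexes))
        ]

    def test_identical_pools_match_exactly(self):
        ages = [30.0, 40, 50, 60]
        sexes = ["M", "M", "F", "F"]
        sz = self._meta("SZ", ages, sexes)
        hc = self._meta("HC", ages, sexes)
        matched = match_controls(hc, sz)
        assert sorted(m.age for m in matched) == sorted(ages)
        mean_diff = np.mean([m.age for m in matched]) - np.mean(ages)
        assert mean_diff == 0.0

    def test_old_outliers_never_selected(self):
        sz = self._meta("SZ", [30.0, 35, 40, 45], ["M", "M", "F", "F"])
        hc = self._meta(
            "HC",
            [30.0, 35, 40, 45] + [90.0] * 28,
            ["M", "M", "F", "F"] + ["M", "F"] * 14,
        )
        matched = match_controls(hc, sz)
        assert all(m.age < 90 for m in matched)

    def test_sex_counts_equal_patients(self):
        sz = self._meta("SZ", [30.0, 40, 50], ["M", "F", "F"])
        hc = self._meta("HC", [25.0, 35, 45, 55, 65], ["M", "M", "F", "F", "F"])
        matched = match_controls(hc, sz)
        assert sum(m.sex == "M" for m in matched) == 1
        assert sum(m.sex == "F" for m in matched) == 2

    def test_insufficient_stratum_rejected(self):
        sz = self._meta("SZ", [30.0, 40], ["M", "M"])
        hc = self._meta("HC", [30.0, 40], ["M", "F"])
        with pytest.raises(ValueError, match="not enough M"):
            match_controls(hc, sz)


class TestRandomPairs:
    def test_pairs_partition_and_are_cross_group(self, rng):
        y = np.r_[np.ones(8, int), np.zeros(8, int)]
        pairs = random_pairs(y, rng)
        flat = sorted(i for p in pairs for i in p)
        assert flat == list(range(16))
        assert all(y[a] != y[b] for a, b in pairs)
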