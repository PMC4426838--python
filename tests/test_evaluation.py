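"""ROC/AUC, threshold sweeps, folds, sign test and the MAF-shift diagnostic."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varmkl.evaluation import (
    ConfusionCounts,
    balanced_accuracy,
    confusion_at_threshold,
    kfold_cv,
    maf_shift,
    roc_auc,
    sign_test,
    threshold_sweep,
)
from varmkl.variant_data import LabeledDataset, Variant
from varmkl.confidence import PlattCalibrator, make_prediction_records


class TestConfusion:
    def test_threshold_below_min_predicts_all_positive(self):
        c = confusion_at_threshold([0.2, 0.8], [1, -1], threshold=0.0)
        assert (c.fn, c.tn) == (0, 0)

    def test_at_threshold_counts_as_positive(self):
        c = confusion_at_threshold([0.9, 0.5, 0.2], [1, -1, -1], threshold=0.5)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 0)

    def test_threshold_above_max_predicts_all_negative(self):
        c = confusion_at_threshold([0.2, 0.8], [1, -1], threshold=0.9)
        assert (c.tp, c.fp) == (0, 0)


class TestBalancedAccuracy:
    def test_perfect_and_degenerate(self):
        assert balanced_accuracy(ConfusionCounts(5, 0, 5, 0)) == 1.0
        assert balanced_accuracy(ConfusionCounts(5, 5, 0, 0)) == 0.5

    def test_arithmetic(self):
        assert balanced_accuracy(ConfusionCounts(90, 30, 70, 10)) == pytest.approx(0.8)

    def test_absent_class_errors(self):
        with pytest.raises(ValueError):
            balanced_accuracy(ConfusionCounts(3, 0, 0, 1))


class TestRocAuc:
    def test_separated_ties_and_pair_enumeration(self):
        assert roc_auc([3.0, 2.0, 1.0, 0.0], [1, 1, -1, -1]) == 1.0
        assert roc_auc([1.0, 1.0, 1.0, 1.0], [1, 1, -1, -1]) == 0.5
        assert roc_auc([0.9, 0.4, 0.8, 0.1], [1, 1, -1, -1]) == pytest.approx(0.75)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_complement_identity_for_tie_free_scores(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        scores = rng.permutation(n).astype(float)  # distinct values
        labels = rng.choice([-1, 1], size=n)
        if len(set(labels)) < 2:
            labels[0], labels[1] = 1, -1
        assert roc_auc(scores, labels) == pytest.approx(
            1.0 - roc_auc(-scores, labels)
        )

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_pairwise_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        scores = rng.integers(0, 4, size=n).astype(float)  # forced ties
        labels = rng.choice([-1, 1], size=n)
        if len(set(labels)) < 2:
            labels[0], labels[1] = 1, -1
        pos = scores[labels == 1]
        neg = scores[labels == -1]
        pairs = [(0.5 if p == q else float(p > q)) for p, q in
                 itertools.product(pos, neg)]
        assert roc_auc(scores, labels) == pytest.approx(np.mean(pairs))


class TestThresholdSweep:
    def test_separable_scores_reach_perfect_balanced_accuracy(self):
        sweep = threshold_sweep([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1])
        assert max(sweep.balanced_accuracy) == 1.0
        i = np.argmax(sweep.balanced_accuracy)
        assert sweep.fpr[i] == 0.0
        assert sweep.optimal_threshold == 0.8  # smallest optimal threshold

    def test_matches_per_threshold_confusion_recomputation(self):
        scores = np.array([0.9, 0.5, 0.2])
        labels = np.array([1, -1, -1])
        sweep = threshold_sweep(scores, labels)
        for thr, bacc, fpr in zip(sweep.thresholds, sweep.balanced_accuracy,
                                  sweep.fpr):
            c = confusion_at_threshold(scores, labels, thr)
            assert bacc == pytest.approx(balanced_accuracy(c))
            assert fpr == pytest.approx(c.fp / (c.fp + c.tn))

    def test_translation_invariance(self):
        scores = np.array([0.9, 0.4, 0.8, 0.1, 0.4])
        labels = np.array([1, 1, -1, -1, -1])
        a = threshold_sweep(scores, labels)
        b = threshold_sweep(scores + 10.0, labels)
        assert b.optimal_threshold == pytest.approx(a.optimal_threshold + 10.0)
        np.testing.assert_allclose(a.balanced_accuracy, b.balanced_accuracy)

    def test_optimum_at_least_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        labels = rng.choice([-1, 1], size=50)
        labels[:2] = [1, -1]
        sweep = threshold_sweep(scores, labels)
        assert max(sweep.balanced_accuracy) >= 0.5


class TestKfold:
    def test_study_scale_split_geometry(self):
        folds = kfold_cv(6000, k=5, seed=0)
        for train, test in folds:
            assert len(test) == 1200 and len(train) == 4800

    def test_partition_property_and_reproducibility(self):
        f1 = kfold_cv(103, k=5, seed=3)
        f2 = kfold_cv(103, k=5, seed=3)
        all_test = np.concatenate([te for _, te in f1])
        assert sorted(all_test) == list(range(103))
        sizes = {len(te) for _, te in f1}
        assert max(sizes) - min(sizes) <= 1
        for (_, a), (_, b) in zip(f1, f2):
            np.testing.assert_array_equal(a, b)

    def test_stratified_preserves_ratio_and_errors_on_tiny_class(self):
        labels = np.r_[np.ones(80), -np.ones(20)]
        folds = kfold_cv(100, k=5, stratified=True, labels=labels, seed=1)
        for _, te in folds:
            assert np.sum(labels[te] == 1) == 16
        with pytest.raises(ValueError):
            kfold_cv(10, k=5, stratified=True, labels=np.r_[np.ones(8), -np.ones(2)])


class TestSignTest:
    def test_five_of_five(self):
        assert sign_test(5, 5) == pytest.approx(0.03125, abs=1e-12)

    def test_zero_wins_whole_tail(self):
        assert sign_test(0, 7) == pytest.approx(1.0)

    def test_four_of_five(self):
        assert sign_test(4, 5) == pytest.approx(6 / 32)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 12), st.data())
    def test_matches_binomial_enumeration(self, n, data):
        from math import comb

        wins = data.draw(st.integers(0, n))
        expected = sum(comb(n, k) for k in range(wins, n + 1)) / 2**n
        assert sign_test(wins, n) == pytest.approx(expected, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            sign_test(3, 0)
        with pytest.raises(ValueError):
            sign_test(6, 5)


class TestMafShift:
    @staticmethod
    def _negatives(mafs):
        return LabeledDataset.from_variants(
            [Variant("chr1", i + 1, "A", "G", -1, maf=m)
             for i, m in enumerate(mafs)]
        )

    @staticmethod
    def _records(posteriors):
        cal = PlattCalibrator(-1.0, 0.0)
        rec = make_prediction_records(np.zeros(len(posteriors)), cal)
        rec["posterior"] = np.asarray(posteriors, float)
        return rec

    def test_no_false_positives_is_an_error(self):
        ds = self._negatives([0.1, 0.2])
        rec = self._records([0.1, 0.2])
        with pytest.raises(ValueError, match="false positive"):
            maf_shift(rec, ds, cutoff=0.9)

    def test_two_variant_toy_gives_unit_bins(self):
        ds = self._negatives([0.03, 0.31])
        rec = self._records([0.99, 0.01])
        fp_hist, tn_hist, shift = maf_shift(rec, ds, cutoff=0.9)
        assert fp_hist.sum() == pytest.approx(1.0)
        assert tn_hist.sum() == pytest.approx(1.0)
        assert np.count_nonzero(fp_hist) == 1
        assert np.count_nonzero(tn_hist) == 1
        assert shift == pytest.approx(0.31 - 0.03)
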