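import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enzdis.evaluation import (
    ConfusionMatrix,
    confusion_from_predictions,
    confusion_from_rates,
    compute_metrics,
    cross_validate,
    kfold_split,
    roc_vertical_average,
)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionMatrix(tp=5, fp=0, tn=5, fn=0))
        assert (m.precision, m.recall, m.accuracy, m.specificity, m.f1, m.mcc) == (
            1, 1, 1, 1, 1, 1)
        assert m.fpr == 0

    def test_hand_computed_example(self):
        m = compute_metrics(ConfusionMatrix(tp=3, fp=1, tn=4, fn=2))
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.accuracy == pytest.approx(0.7)
        assert m.specificity == pytest.approx(0.8)
        assert m.f1 == pytest.approx(2 / 3)
        assert m.mcc == pytest.approx(10 / math.sqrt(600))
        assert m.fpr == pytest.approx(0.2)

    def test_zero_over_zero_flagged(self):
        m = compute_metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=5))
        assert m.precision == 0.0
        assert "precision" in m.degenerate and "f1" in m.degenerate

    def test_invalid_matrix(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, tn=1, fn=0)
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=0, fp=0, tn=0, fn=0)


cells = st.integers(min_value=0, max_value=50)


class TestMetricOracle:
    @given(cells, cells, cells, cells)
    @settings(max_examples=200, deadline=None)
    def test_equals_bruteforce_from_raw_pairs(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        # reconstruct raw (prediction, gold) pairs and recount from scratch
        pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
        gold = [1] * tp + [0] * fp + [0] * tn + [1] * fn
        cm = confusion_from_predictions(pred, gold)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (tp, fp, tn, fn)
        m = compute_metrics(cm)
        n = len(pred)
        agree = sum(p == g for p, g in zip(pred, gold))
        assert m.accuracy == pytest.approx(agree / n)
        if tp + fp:
            assert m.precision == pytest.approx(tp / (tp + fp))
        if tp + fn:
            assert m.recall == pytest.approx(tp / (tp + fn))

    @given(cells, cells, cells, cells)
    @settings(max_examples=200, deadline=None)
    def test_mcc_class_swap_symmetry(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        m = compute_metrics(ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn))
        swapped = compute_metrics(ConfusionMatrix(tp=tn, fp=fn, tn=tp, fn=fp))
        assert abs(m.mcc) == pytest.approx(abs(swapped.mcc))


class TestConfusionFromRates:
    def test_perfect_rates(self):
        cm = confusion_from_rates(1.0, 1.0, 0.3)
        assert cm.fp == 0 and cm.fn == 0

    def test_balanced_reconstruction_from_published_rates(self):
        # recall 0.192, specificity 0.967 under a balanced test set
        m = compute_metrics(confusion_from_rates(0.192, 0.967, 0.5))
        assert m.accuracy == pytest.approx(0.580, abs=5e-4)
        assert m.mcc == pytest.approx(0.252, abs=1e-3)
        m2 = compute_metrics(confusion_from_rates(0.548, 0.986, 0.5))
        assert m2.mcc == pytest.approx(0.594, abs=1e-3)
        assert m2.precision == pytest.approx(0.976, abs=2e-3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion_from_rates(1.1, 0.5, 0.5)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99), st.floats(0.05, 0.95))
    @settings(max_examples=100, deadline=None)
    def test_left_inverse_on_recall_and_specificity(self, rec, spec, prev):
        m = compute_metrics(confusion_from_rates(rec, spec, prev))
        assert m.recall == pytest.approx(rec)
        assert m.specificity == pytest.approx(spec)


class TestKfoldSplit:
    def test_even_split(self):
        folds = kfold_split([0, 1] * 50, 5, seed=0)
        assert sorted(len(f) for f in folds) == [20] * 5

    def test_remainder_rule(self):
        y = [0] * 51 + [1] * 50
        folds = kfold_split(y, 5, seed=0)
        assert sorted(len(f) for f in folds) == [20, 20, 20, 20, 21]

    def test_partition_and_stratification(self):
        y = np.array([0] * 30 + [1] * 20)
        folds = kfold_split(y, 5, seed=3)
        allidx = np.concatenate(folds)
        assert sorted(allidx) == list(range(50))
        for f in folds:
            assert y[f].sum() == 4  # 20 positives over 5 folds

    def test_determinism_and_seed_sensitivity(self):
        y = [0, 1] * 20
        a = kfold_split(y, 4, seed=7)
        b = kfold_split(y, 4, seed=7)
        c = kfold_split(y, 4, seed=8)
        assert all(np.array_equal(x, z) for x, z in zip(a, b))
        assert not all(np.array_equal(x, z) for x, z in zip(a, c))

    def test_errors(self):
        with pytest.raises(ValueError):
            kfold_split([0, 1, 0], 4, seed=0)
        with pytest.raises(ValueError):
            kfold_split([0, 1, 0], 1, seed=0)


def _threshold_rule(X_train, y_train, X_test):
    """Stand-in learner: predict by the sign of the single feature's mean split."""
    X_train = np.asarray(X_train, dtype=float).ravel()
    X_test = np.asarray(X_test, dtype=float).ravel()
    thr = X_train.mean()
    scores = X_test - thr
    return (scores > 0).astype(int), scores


class TestCrossValidate:
    def test_separable_data_perfect_folds(self):
        X = [[v] for v in list(np.linspace(0, 1, 30)) + list(np.linspace(9, 10, 30))]
        y = [0] * 30 + [1] * 30
        cv = cross_validate(X, y, _threshold_rule, k=5, seed=0)
        assert cv.mean["f1"] == pytest.approx(1.0)
        assert cv.sd["f1"] == pytest.approx(0.0)
        assert len(cv.folds) == 5

    def test_random_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(0)
        X = [[v] for v in rng.normal(size=1000)]
        y = rng.integers(0, 2, size=1000)
        cv = cross_validate(X, y, _threshold_rule, k=5, seed=0)
        assert cv.mean["accuracy"] == pytest.approx(0.5, abs=0.05)

    def test_single_class_training_fold_skipped(self, caplog):
        X = [[0.0], [1.0], [2.0], [3.0]]
        y = [1, 0, 0, 0]
        with caplog.at_level("WARNING"):
            cv = cross_validate(X, y, _threshold_rule, k=4, seed=0)
        assert cv.skipped == 1
        assert len(cv.folds) == 3


class TestRocVerticalAverage:
    def test_identical_folds_average_to_the_fold_curve(self):
        y = [0, 0, 1, 1, 0, 1]
        s = [0.1, 0.4, 0.35, 0.8, 0.2, 0.7]
        one = roc_vertical_average([(y, s)])
        many = roc_vertical_average([(y, s)] * 5)
        assert np.allclose(one.tpr, many.tpr)
        assert one.auc == pytest.approx(many.auc)

    def test_perfect_ranking_auc_one(self):
        folds = [([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])] * 3
        curve = roc_vertical_average(folds)
        assert curve.auc == pytest.approx(1.0)
        assert curve.tpr[-1] == pytest.approx(1.0)

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(1)
        folds = []
        for _ in range(5):
            y = rng.integers(0, 2, size=1000)
            s = rng.normal(size=1000)
            folds.append((y, s))
        curve = roc_vertical_average(folds)
        assert curve.auc == pytest.approx(0.5, abs=0.05)

    def test_monotone_transform_invariance(self):
        y = [0, 1, 0, 1, 1, 0, 1]
        s = np.array([0.1, 0.9, 0.3, 0.5, 0.8, 0.2, 0.4])
        a = roc_vertical_average([(y, s)])
        b = roc_vertical_average([(y, np.exp(3 * s))])
        assert np.allclose(a.tpr, b.tpr)
        assert a.auc == pytest.approx(b.auc)

    def test_single_label_fold_excluded(self, caplog):
        good = ([0, 1, 0, 1], [0.2, 0.9, 0.4, 0.7])
        bad = ([1, 1, 1], [0.5, 0.6, 0.7])
        with caplog.at_level("WARNING"):
            curve = roc_vertical_average([good, bad])
        ref = roc_vertical_average([good])
        assert np.allclose(curve.tpr, ref.tpr)

    def test_all_single_label_is_error(self):
        with pytest.raises(ValueError):
            roc_vertical_average([([1, 1], [0.1, 0.2])])

    def test_fpr_grid_monotone_curve_endpoints(self):
        y = [0, 1, 1, 0, 1]
        s = [0.3, 0.6, 0.9, 0.5, 0.1]
        curve = roc_vertical_average([(y, s)])
        assert curve.fpr[0] == 0.0 and curve.fpr[-1] == 1.0
        assert curve.tpr[-1] == pytest.approx(1.0)
        assert np.all(np.diff(curve.fpr) >= 0)
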