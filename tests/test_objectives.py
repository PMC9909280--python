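"""Tests for losses, class weights and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lfianet import objectives as obj


def random_simplex_batch(rng, m=16, c=4):
    p = rng.random((m, c)) + 1e-3
    return p / p.sum(axis=1, keepdims=True)


def onehot(labels, c=4):
    out = np.zeros((len(labels), c))
    out[np.arange(len(labels)), labels] = 1.0
    return out


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        y = onehot([0, 1, 2, 3])
        assert obj.cross_entropy_loss(y, y) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_prediction_is_log4(self):
        pred = np.full((5, 4), 0.25)
        truth = onehot([0, 3, 1, 2, 2])
        assert obj.cross_entropy_loss(pred, truth) == pytest.approx(np.log(4.0))

    def test_matches_per_sample_loop_oracle(self, rng):
        pred = random_simplex_batch(rng)
        labels = rng.integers(0, 4, size=len(pred))
        truth = onehot(labels)
        oracle = -np.mean([np.log(pred[j, labels[j]]) for j in range(len(pred))])
        assert obj.cross_entropy_loss(pred, truth) == pytest.approx(oracle, rel=1e-12)

    def test_zero_probability_clamped_finite(self):
        pred = np.array([[0.0, 1.0, 0.0, 0.0]])
        truth = onehot([0])
        loss = obj.cross_entropy_loss(pred, truth)
        assert np.isfinite(loss)
        assert loss == pytest.approx(-np.log(obj.EPS))


class TestDice:
    def test_identical_masks(self, rng):
        m = (rng.random(512) < 0.3).astype(float)
        assert obj.dsc(m, m) == pytest.approx(1.0)

    def test_disjoint_masks(self):
        a = np.zeros(512)
        b = np.zeros(512)
        a[:100] = 1
        b[200:300] = 1
        assert obj.dsc(a, b) == 0.0

    def test_hand_counted_overlap(self):
        # |A|=110, |B|=90, overlap 80 -> 2*80/200 = 0.8
        a = np.zeros(512)
        b = np.zeros(512)
        a[0:110] = 1
        b[30:120] = 1
        assert obj.dsc(a, b) == pytest.approx(2 * 80 / 200)

    def test_both_empty_is_one(self):
        assert obj.dsc(np.zeros(512), np.zeros(512)) == 1.0

    def test_dsc_loss_endpoints_and_oracle(self, rng):
        m = (rng.random((6, 512)) < 0.25).astype(float)
        assert obj.dsc_loss(m, m) == pytest.approx(0.0)
        flipped = 1.0 - m
        assert obj.dsc_loss(flipped, m) == pytest.approx(1.0)
        soft = rng.random((6, 512))
        oracle = 1.0 - np.mean([obj.dsc(soft[j], m[j]) for j in range(6)])
        assert obj.dsc_loss(soft, m) == pytest.approx(oracle, rel=1e-12)


class TestWBCE:
    def test_perfect_prediction_near_zero(self, rng):
        m = (rng.random((4, 512)) < 0.3).astype(float)
        assert obj.wbce_loss(m, m, 0.6, 0.4) == pytest.approx(0.0, abs=1e-5)

    def test_half_weights_equal_half_unweighted_bce(self, rng):
        pred = rng.uniform(0.01, 0.99, size=(5, 64))
        truth = (rng.random((5, 64)) < 0.4).astype(float)
        bce = -np.mean(truth * np.log(pred) + (1 - truth) * np.log(1 - pred))
        assert obj.wbce_loss(pred, truth, 0.5, 0.5) == pytest.approx(0.5 * bce, rel=1e-9)

    def test_single_point_hand_value(self):
        # y=1, o=0.1, w1=0.6 -> -0.6*ln(0.1) = 0.6*ln(10)
        loss = obj.wbce_loss(np.array([[0.1]]), np.array([[1.0]]), w0=0.4, w1=0.6)
        assert loss == pytest.approx(0.6 * np.log(10.0), rel=1e-9)

    def test_monotone_in_true_positive_probability(self):
        truth = np.ones((1, 8))
        losses = [obj.wbce_loss(np.full((1, 8), o), truth, 0.6, 0.4)
                  for o in np.linspace(0.05, 0.95, 10)]
        assert np.all(np.diff(losses) < 0)

    def test_combined_is_sum_of_components(self, rng):
        pred = rng.uniform(0.01, 0.99, size=(4, 128))
        truth = (rng.random((4, 128)) < 0.3).astype(float)
        assert obj.combined_loss(pred, truth, 0.6, 0.4) == pytest.approx(
            obj.wbce_loss(pred, truth, 0.6, 0.4) + obj.dsc_loss(pred, truth))


class TestClassWeight:
    def test_endpoints(self):
        assert obj.class_weight(100, 100) == 0.0
        assert obj.class_weight(100, 0) == 1.0

    @given(st.integers(1, 10**6), st.data())
    @settings(max_examples=50, deadline=None)
    def test_binary_partition_weights_sum_to_one(self, n, data):
        n1 = data.draw(st.integers(0, n))
        w1 = obj.class_weight(n, n1)
        w0 = obj.class_weight(n, n - n1)
        assert w0 + w1 == pytest.approx(1.0, abs=1e-12)

    def test_invalid_total_rejected(self):
        with pytest.raises(ValueError):
            obj.class_weight(0, 0)


class TestMetrics:
    def test_accuracy_examples(self):
        assert obj.accuracy([1, 2, 3], [1, 2, 3]) == 1.0
        assert obj.accuracy([1, 1, 1], [2, 3, 4]) == 0.0
        # five errors out of 1,230 scored samples
        true = np.ones(1230)
        pred = true.copy()
        pred[:5] = 2
        assert obj.accuracy(pred, true) == pytest.approx(1225 / 1230)

    def test_iou_hand_count(self):
        a = np.zeros(512)
        b = np.zeros(512)
        a[0:100] = 1   # |A|=100
        b[20:120] = 1  # |B|=100, overlap 80, union 120
        assert obj.iou(a, b) == pytest.approx(80 / 120)

    def test_iou_conventions(self, rng):
        m = (rng.random(512) < 0.3).astype(float)
        assert obj.iou(m, m) == 1.0
        assert obj.iou(np.zeros(512), np.zeros(512)) == 1.0

    def test_precision_recall_against_confusion_counts(self, rng):
        pred = (rng.random((8, 512)) < 0.3).astype(float)
        truth = (rng.random((8, 512)) < 0.3).astype(float)
        tp = np.sum((pred == 1) & (truth == 1))
        fp = np.sum((pred == 1) & (truth == 0))
        fn = np.sum((pred == 0) & (truth == 1))
        p, r = obj.precision_recall(pred, truth)
        assert p == pytest.approx(tp / (tp + fp))
        assert r == pytest.approx(tp / (tp + fn))

    def test_precision_one_when_pred_subset_of_truth(self):
        truth = np.zeros(512)
        truth[100:200] = 1
        pred = np.zeros(512)
        pred[120:150] = 1
        p, r = obj.precision_recall(pred, truth)
        assert p == 1.0
        assert r == pytest.approx(30 / 100)

    def test_confusion_matrix(self, rng):
        true = rng.integers(1, 5, size=200)
        pred = rng.integers(1, 5, size=200)
        mat = obj.confusion(pred, true)
        assert mat.sum() == 200
        # pairwise counting oracle; rows are predicted, columns true
        for i in range(4):
            for j in range(4):
                assert mat[i, j] == np.sum((pred == i + 1) & (true == j + 1))
        perfect = obj.confusion(true, true)
        assert np.all(perfect == np.diag(np.diag(perfect)))

    def test_order_invariance(self, rng):
        true = rng.integers(1, 5, size=100)
        pred = rng.integers(1, 5, size=100)
        perm = rng.permutation(100)
        assert obj.accuracy(pred, true) == obj.accuracy(pred[perm], true[perm])
        masks_p = (rng.random((10, 64)) < 0.4).astype(float)
        masks_t = (rng.random((10, 64)) < 0.4).astype(float)
        shuffle = rng.permutation(10)
        assert obj.iou(masks_p, masks_t) == pytest.approx(
            obj.iou(masks_p[shuffle], masks_t[shuffle]), rel=1e-12)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=40, deadline=None)
def test_dice_iou_identity(seed):
    """dice = 2*iou/(1+iou) per sample, to 1e-12, on random binary masks."""
    rng = np.random.default_rng(seed)
    a = (rng.random(512) < rng.uniform(0.05, 0.6)).astype(float)
    b = (rng.random(512) < rng.uniform(0.05, 0.6)).astype(float)
    d = obj.dsc(a, b)
    i = obj.iou(a, b)
    assert abs(d - 2 * i / (1 + i)) < 1e-12
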