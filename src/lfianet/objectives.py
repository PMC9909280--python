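"""Loss functions and evaluation metrics.

Losses
------
* ``cross_entropy_loss`` for the four-class classifier:
  ``L_CE = -(1/M) sum_j sum_i y_ij log o_ij``.
* ``dsc_loss`` = 1 - mean Dice similarity over the batch.
* ``wbce_loss`` — weighted binary cross-entropy with background weight ``w0``
  and region weight ``w1``:
  ``L_WBCE = -(1/(M N)) sum_j sum_i [w1 y log o + w0 (1-y) log(1-o)]``.
* ``combined_loss`` = WBCE + DSC, the default segmentation objective.

All cross-entropy terms use the natural logarithm (this scales the loss but
not its optimum) and clamp probabilities to ``[eps, 1-eps]`` with
``eps = 1e-7`` so a confidently wrong prediction yields a large finite loss,
never an infinity.

Metrics
-------
``accuracy``, ``iou`` (Jaccard), ``dsc`` (Dice), ``precision_recall`` and the
4x4 ``confusion`` matrix (rows = predicted class, columns = true class).
When both masks are empty, Dice and IoU are defined as 1 — an empty
prediction of an empty region is a perfect one — so class-degenerate batches
do not poison training or evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn

EPS = 1e-7


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


def _as_batch(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    return a[None] if a.ndim == 1 else a


# ---------------------------------------------------------------------------
# losses


def cross_entropy_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean categorical cross-entropy; ``pred`` rows are probability simplices,
    ``truth`` rows are one-hot labels."""
    pred = _as_batch(pred)
    truth = _as_batch(truth)
    return float(-(truth * np.log(_clamp(pred))).sum() / pred.shape[0])


def dsc(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Dice similarity ``2|A n B| / (|A| + |B|)`` for one mask pair.

    Accepts soft predictions (elementwise product/sum form).  Both masks
    empty -> 1.
    """
    a = np.asarray(pred_mask, dtype=np.float64)
    b = np.asarray(truth_mask, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a * b).sum() / denom)


def dsc_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """``1 - (1/M) sum_j DSC_j`` over a batch of masks."""
    pred = _as_batch(pred)
    truth = _as_batch(truth)
    return float(1.0 - np.mean([dsc(p, t) for p, t in zip(pred, truth)]))


def wbce_loss(pred: np.ndarray, truth: np.ndarray, w0: float, w1: float) -> float:
    """Weighted binary cross-entropy; ``w1`` weights region points (label 1),
    ``w0`` background points."""
    if w0 < 0 or w1 < 0:
        raise ValueError("weights must be nonnegative")
    pred = _clamp(_as_batch(pred))
    truth = _as_batch(truth)
    m, n = pred.shape
    terms = w1 * truth * np.log(pred) + w0 * (1.0 - truth) * np.log(1.0 - pred)
    return float(-terms.sum() / (m * n))


def combined_loss(pred: np.ndarray, truth: np.ndarray, w0: float, w1: float) -> float:
    """WBCE + DSC, the combined segmentation objective."""
    return wbce_loss(pred, truth, w0, w1) + dsc_loss(pred, truth)


def class_weight(n_total: int, n_class: int) -> float:
    """Data-driven point weight ``w_c = (N - N_c) / N``."""
    if n_total <= 0:
        raise ValueError("total point count must be positive")
    if not (0 <= n_class <= n_total):
        raise ValueError("class count must lie in [0, N]")
    return (n_total - n_class) / n_total


# ---------------------------------------------------------------------------
# loss gradients with respect to pre-activation logits (used by training)


def ce_grad_logits(probs: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """d L_CE / d logits for a softmax head: ``(o - y) / M``."""
    return ((probs - onehot) / probs.shape[0]).astype(_nn.DTYPE)


def wbce_grad_logits(probs: np.ndarray, truth: np.ndarray,
                     w0: float, w1: float) -> np.ndarray:
    """d L_WBCE / d logits for a sigmoid head."""
    m, n = probs.shape
    o = np.clip(probs, EPS, 1.0 - EPS)
    return ((w0 * (1.0 - truth) * o - w1 * truth * (1.0 - o)) / (m * n)).astype(_nn.DTYPE)


def dsc_grad_logits(probs: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """d L_DSC / d logits for a sigmoid head (soft Dice, per-sample)."""
    m = probs.shape[0]
    o = probs.astype(np.float64)
    y = truth.astype(np.float64)
    s_y = y.sum(axis=1, keepdims=True)
    s_o = o.sum(axis=1, keepdims=True)
    s_yo = (y * o).sum(axis=1, keepdims=True)
    denom = s_y + s_o
    # both-empty samples have zero gradient under the DSC=1 convention
    safe = np.where(denom == 0, 1.0, denom)
    ddsc_do = (2.0 * y * safe - 2.0 * s_yo) / safe**2
    ddsc_do = np.where(denom == 0, 0.0, ddsc_do)
    dl_do = -ddsc_do / m
    return (dl_do * o * (1.0 - o)).astype(_nn.DTYPE)


def combined_grad_logits(probs: np.ndarray, truth: np.ndarray,
                         w0: float, w1: float) -> np.ndarray:
    return wbce_grad_logits(probs, truth, w0, w1) + dsc_grad_logits(probs, truth)


# ---------------------------------------------------------------------------
# metrics


def accuracy(pred_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Proportion of correctly predicted samples."""
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    if pred_labels.shape != true_labels.shape:
        raise ValueError("label arrays differ in shape")
    return float(np.mean(pred_labels == true_labels))


def iou(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Intersection over union; batch input returns the mean over samples.

    Per sample: ``sum(y o) / (sum y + sum o - sum(y o))``; both masks empty
    -> 1.
    """
    pred = _as_batch(pred_mask)
    truth = _as_batch(truth_mask)
    vals = []
    for p, t in zip(pred, truth):
        inter = (p * t).sum()
        union = p.sum() + t.sum() - inter
        vals.append(1.0 if union == 0 else inter / union)
    return float(np.mean(vals))


def precision_recall(pred_mask: np.ndarray, truth_mask: np.ndarray) -> tuple[float, float]:
    """Pointwise precision = TP/(TP+FP) and recall = TP/(TP+FN), pooled over
    all points of all samples.  An empty denominator yields 1.0."""
    pred = _as_batch(pred_mask).astype(bool)
    truth = _as_batch(truth_mask).astype(bool)
    tp = float(np.sum(pred & truth))
    fp = float(np.sum(pred & ~truth))
    fn = float(np.sum(~pred & truth))
    precision = 1.0 if tp + fp == 0 else tp / (tp + fp)
    recall = 1.0 if tp + fn == 0 else tp / (tp + fn)
    return precision, recall


def confusion(pred_labels: np.ndarray, true_labels: np.ndarray,
              n_classes: int = 4) -> np.ndarray:
    """Confusion matrix with rows = predicted label, columns = true label."""
    pred = np.asarray(pred_labels, dtype=np.int64)
    true = np.asarray(true_labels, dtype=np.int64)
    if pred.shape != true.shape:
        raise ValueError("label arrays differ in shape")
    mat = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(mat, (pred - 1, true - 1), 1)
    return mat


@dataclass(frozen=True)
class SegMetrics:
    """Segmentation report: batch-mean IoU/Dice plus pooled precision/recall."""

    iou: float
    dice: float
    recall: float
    precision: float

    def as_dict(self) -> dict[str, float]:
        return {"iou": self.iou, "dice": self.dice,
                "recall": self.recall, "precision": self.precision}


def segmentation_metrics(pred_masks: np.ndarray, truth_masks: np.ndarray) -> SegMetrics:
    pred = _as_batch(pred_masks)
    truth = _as_batch(truth_masks)
    dice = float(np.mean([dsc(p, t) for p, t in zip(pred, truth)]))
    precision, recall = precision_recall(pred, truth)
    return SegMetrics(iou=iou(pred, truth), dice=dice,
                      recall=recall, precision=precision)
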