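"""Training, evaluation and the weight/cutoff grid search.

Both networks train with Adam (lr 0.001), batch size 8, on an 80/20
stratified split: the classifier for 30 epochs under cross-entropy, the
segmenter for 100 epochs under WBCE + DSC with (w0, w1) = (0.6, 0.4) and an
inference cutoff of 0.6.  The checkpoint with the best validation metric
(accuracy / IoU) is the one returned.

Every source of randomness — dataset split, batch shuffling, weight
initialization, dropout — derives from ``TrainConfig.seed``, so a fixed
(config, dataset) pair reproduces every reported metric bit-for-bit on a
single CPU thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import objectives as obj
from ._nn import Adam
from .models import (
    ClassifierConfig,
    PeakClassifier,
    SegmenterConfig,
    UNetSegmenter,
)
from .preprocess import batch_model_input
from .synthdata import LabeledTrace

LOSS_TAGS = ("CE", "WBCE", "DSC", "WBCE+DSC")


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    epochs: int = 30
    learning_rate: float = 0.001
    loss: str = "CE"
    w0: float = 0.6
    w1: float = 0.4
    cutoff: float = 0.6
    weight_mode: str = "fixed"  # "fixed" uses (w0, w1); "data" uses w_c=(N-Nc)/N per batch
    split_ratio: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.loss not in LOSS_TAGS:
            raise ValueError(f"loss must be one of {LOSS_TAGS}")
        if self.w0 < 0 or self.w1 < 0:
            raise ValueError("loss weights must be nonnegative")
        if not (0 < self.split_ratio < 1):
            raise ValueError("split_ratio must be in (0, 1)")
        if self.weight_mode not in ("fixed", "data"):
            raise ValueError("weight_mode must be 'fixed' or 'data'")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_metric: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_metric(self) -> float:
        return self.val_metric[self.best_epoch]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "val_metric": self.val_metric,
        })


def split_dataset(dataset: list[LabeledTrace], ratio: float = 0.8,
                  seed: int = 0) -> tuple[list[LabeledTrace], list[LabeledTrace]]:
    """Seeded stratified split into (train, validation).

    Each class is shuffled and split at ``ratio`` separately, so class
    proportions are preserved; the union is the full dataset.
    """
    if not (0 < ratio < 1):
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = sorted({t.label for t in dataset})
    train: list[LabeledTrace] = []
    val: list[LabeledTrace] = []
    for label in labels:
        members = [i for i, t in enumerate(dataset) if t.label == label]
        if not members:
            raise ValueError(f"class {label} is empty")
        perm = rng.permutation(len(members))
        n_train = int(round(ratio * len(members)))
        if n_train == 0 or n_train == len(members):
            raise ValueError(f"split leaves class {label} empty on one side")
        for j in perm[:n_train]:
            train.append(dataset[members[j]])
        for j in perm[n_train:]:
            val.append(dataset[members[j]])
    return train, val


def _tensorize(dataset: list[LabeledTrace]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(inputs (n,2,512) float32, labels (n,), masks (n,512) float32)."""
    raw = np.stack([t.values for t in dataset])
    x = batch_model_input(raw)
    y = np.array([t.label for t in dataset], dtype=np.int64)
    masks = np.stack([t.mask for t in dataset]).astype(np.float32)
    return x, y, masks


def _onehot(labels: np.ndarray, n_classes: int = 4) -> np.ndarray:
    out = np.zeros((len(labels), n_classes), dtype=np.float32)
    out[np.arange(len(labels)), labels - 1] = 1.0
    return out


def train_classifier(
    train: list[LabeledTrace],
    val: list[LabeledTrace],
    config: TrainConfig | None = None,
    model_config: ClassifierConfig | None = None,
) -> tuple[PeakClassifier, TrainHistory]:
    """Train the peak-shape classifier; returns the best-validation-accuracy
    checkpoint and the per-epoch history."""
    cfg = config or TrainConfig()
    x_tr, y_tr, _ = _tensorize(train)
    x_va, y_va, _ = _tensorize(val)
    onehot_tr = _onehot(y_tr)
    model = PeakClassifier(model_config, seed=cfg.seed)
    optimizer = Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    history = TrainHistory()
    best_state = model.get_state()
    best_metric = -np.inf
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(x_tr))
        losses = []
        for start in range(0, len(perm), cfg.batch_size):
            sel = perm[start:start + cfg.batch_size]
            probs = model.forward(x_tr[sel], training=True)
            losses.append(obj.cross_entropy_loss(probs, onehot_tr[sel]))
            optimizer.zero_grad()
            model.backward(obj.ce_grad_logits(probs, onehot_tr[sel]))
            optimizer.step()
        train_loss = float(np.mean(losses))
        if not np.isfinite(train_loss):
            raise TrainingDivergedError(f"non-finite loss at epoch {epoch + 1}")
        val_probs = _forward_batched(model, x_va)
        val_loss = obj.cross_entropy_loss(val_probs, _onehot(y_va))
        val_acc = obj.accuracy(val_probs.argmax(axis=1) + 1, y_va)
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.val_metric.append(val_acc)
        if val_acc > best_metric:
            best_metric = val_acc
            best_state = model.get_state()
            history.best_epoch = epoch
    model.set_state(best_state)
    return model, history


def _seg_loss_and_grad(tag: str, probs: np.ndarray, masks: np.ndarray,
                       w0: float, w1: float) -> tuple[float, np.ndarray]:
    if tag == "WBCE":
        return (obj.wbce_loss(probs, masks, w0, w1),
                obj.wbce_grad_logits(probs, masks, w0, w1))
    if tag == "DSC":
        return obj.dsc_loss(probs, masks), obj.dsc_grad_logits(probs, masks)
    if tag == "WBCE+DSC":
        return (obj.combined_loss(probs, masks, w0, w1),
                obj.combined_grad_logits(probs, masks, w0, w1))
    raise ValueError(f"{tag!r} is not a segmentation loss")


def train_segmenter(
    train: list[LabeledTrace],
    val: list[LabeledTrace],
    config: TrainConfig | None = None,
    model_config: SegmenterConfig | None = None,
) -> tuple[UNetSegmenter, TrainHistory]:
    """Train the integral-region segmenter; returns the checkpoint with the
    best validation IoU (masks thresholded at ``config.cutoff``)."""
    cfg = config or TrainConfig(loss="WBCE+DSC", epochs=100)
    tag = cfg.loss if cfg.loss != "CE" else "WBCE+DSC"
    x_tr, _, m_tr = _tensorize(train)
    x_va, _, m_va = _tensorize(val)
    model = UNetSegmenter(model_config, seed=cfg.seed)
    optimizer = Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    history = TrainHistory()
    best_state = model.get_state()
    best_metric = -np.inf
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(x_tr))
        losses = []
        for start in range(0, len(perm), cfg.batch_size):
            sel = perm[start:start + cfg.batch_size]
            probs = model.forward(x_tr[sel], training=True)
            truth = m_tr[sel]
            if cfg.weight_mode == "data":
                n = truth.size
                n1 = float(truth.sum())
                w1 = obj.class_weight(n, int(n1))
                w0 = obj.class_weight(n, int(n - n1))
            else:
                w0, w1 = cfg.w0, cfg.w1
            loss, dlogits = _seg_loss_and_grad(tag, probs, truth, w0, w1)
            losses.append(loss)
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step()
        train_loss = float(np.mean(losses))
        if not np.isfinite(train_loss):
            raise TrainingDivergedError(f"non-finite loss at epoch {epoch + 1}")
        val_probs = _forward_batched(model, x_va)
        val_loss, _ = _seg_loss_and_grad(tag, val_probs, m_va, cfg.w0, cfg.w1)
        val_iou = obj.iou((val_probs >= cfg.cutoff).astype(np.float64), m_va)
        history.train_loss.append(train_loss)
        history.val_loss.append(float(val_loss))
        history.val_metric.append(val_iou)
        if val_iou > best_metric:
            best_metric = val_iou
            best_state = model.get_state()
            history.best_epoch = epoch
    model.set_state(best_state)
    return model, history


def _forward_batched(model, x: np.ndarray, batch: int = 64) -> np.ndarray:
    outs = [model.forward(x[i:i + batch], training=False)
            for i in range(0, len(x), batch)]
    return np.concatenate(outs, axis=0)


def evaluate(model, val: list[LabeledTrace], cutoff: float = 0.6) -> dict:
    """Deterministic validation report.

    Classifier: accuracy plus the 4x4 confusion matrix (rows = predicted).
    Segmenter: IoU, Dice, recall, precision of cutoff-thresholded masks.
    """
    if isinstance(model, PeakClassifier):
        x, y, _ = _tensorize(val)
        pred = _forward_batched(model, x).argmax(axis=1) + 1
        return {
            "accuracy": obj.accuracy(pred, y),
            "confusion": obj.confusion(pred, y).tolist(),
        }
    if isinstance(model, UNetSegmenter):
        x, _, masks = _tensorize(val)
        pred = (_forward_batched(model, x) >= cutoff).astype(np.float64)
        return obj.segmentation_metrics(pred, masks).as_dict()
    raise TypeError(f"cannot evaluate {type(model).__name__}")


DEFAULT_WEIGHT_RATIOS = ((0.3, 0.7), (0.4, 0.6), (0.5, 0.5), (0.6, 0.4), (0.7, 0.3))
DEFAULT_CUTOFFS = (0.3, 0.4, 0.5, 0.6, 0.7)


def grid_search(
    train: list[LabeledTrace],
    val: list[LabeledTrace],
    weight_ratios: tuple[tuple[float, float], ...] = DEFAULT_WEIGHT_RATIOS,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    config: TrainConfig | None = None,
    model_config: SegmenterConfig | None = None,
) -> pd.DataFrame:
    """Cross experiment on WBCE weights and cutoff thresholds.

    One segmenter is trained per weight ratio (the cutoff only affects
    inference) and evaluated at every cutoff; the result is an IoU table
    with one row per ``w0:w1`` ratio and one column per cutoff.  Each run
    uses the same seed as a stand-alone ``train_segmenter`` call with that
    ratio, so any cell can be reproduced independently.
    """
    base = config or TrainConfig(loss="WBCE+DSC", epochs=100)
    x_va, _, m_va = _tensorize(val)
    rows = {}
    for w0, w1 in weight_ratios:
        cfg = replace(base, w0=w0, w1=w1)
        model, _ = train_segmenter(train, val, cfg, model_config)
        probs = _forward_batched(model, x_va)
        rows[f"{w0:g}:{w1:g}"] = [
            obj.iou((probs >= cutoff).astype(np.float64), m_va) for cutoff in cutoffs
        ]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"cutoff={c:g}" for c in cutoffs])
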