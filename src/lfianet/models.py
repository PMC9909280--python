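"""The two network architectures.

``PeakClassifier`` — a 10-layer 1D CNN that assigns a trace to one of the
four peak-shape classes.  Seven conv(3)+ReLU+maxpool(2) stages reduce the
512-point, two-channel input to four positions of 1,024 channels; an eighth
convolution widens to 2,048 channels; a global max over the remaining
positions yields a flat 2,048-vector; dropout + fully-connected + softmax
produce the four class probabilities.

``UNetSegmenter`` — a 1D U-Net that marks, per point, whether the point
belongs to a C/T integral region.  Four encoder units of
[conv(3)+batchnorm+ReLU]x2 followed by average pooling halve the length
512 -> 32; a symmetric decoder with nearest-neighbor upsampling and skip
concatenation restores the resolution; a final 1-channel convolution +
sigmoid gives the probability mask.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ._nn import (
    AvgPool1d,
    BatchNorm1d,
    Conv1d,
    Dropout,
    GlobalMaxPool,
    Layer,
    Linear,
    MaxPool1d,
    Param,
    ReLU,
    Sequential,
    UpsampleNearest,
    sigmoid,
    softmax,
)


class ConfigError(ValueError):
    """Raised when a model config violates its architectural invariants."""


@dataclass(frozen=True)
class ClassifierConfig:
    input_length: int = 512
    input_channels: int = 2
    conv_channels: tuple[int, ...] = (16, 32, 64, 128, 256, 512, 1024)
    expansion_channels: int = 2048
    kernel_size: int = 3
    dropout_rate: float = 0.5
    n_classes: int = 4

    def __post_init__(self) -> None:
        n_stages = len(self.conv_channels)
        if self.input_length % (2 ** n_stages) != 0 or self.input_length // (2 ** n_stages) < 1:
            raise ConfigError("input_length must be divisible by 2^n_stages")
        if self.kernel_size % 2 != 1:
            raise ConfigError("kernel_size must be odd (same padding)")
        if not (0 <= self.dropout_rate < 1):
            raise ConfigError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class SegmenterConfig:
    input_length: int = 512
    input_channels: int = 2
    encoder_features: tuple[int, ...] = (16, 32, 64, 128)
    kernel_size: int = 3
    batch_norm: bool = True

    def __post_init__(self) -> None:
        depth = len(self.encoder_features)
        if self.input_length % (2 ** depth) != 0:
            raise ConfigError("input_length must be divisible by 2^encoder_depth")
        if self.kernel_size % 2 != 1:
            raise ConfigError("kernel_size must be odd (same padding)")


class _Model:
    """Shared checkpointing and parameter plumbing."""

    config: object
    seed: int

    def params(self) -> list[Param]:
        raise NotImplementedError

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for a, s in zip(self.state_arrays(), state, strict=True):
            a[...] = s


class PeakClassifier(_Model):
    def __init__(self, config: ClassifierConfig | None = None, seed: int = 0):
        self.config = config or ClassifierConfig()
        self.seed = seed
        rng = np.random.default_rng(seed)
        cfg = self.config
        layers: list[Layer] = []
        c_in = cfg.input_channels
        for stage, c_out in enumerate(cfg.conv_channels):
            layers += [Conv1d(c_in, c_out, cfg.kernel_size, rng,
                              needs_input_grad=stage > 0),
                       ReLU(), MaxPool1d()]
            c_in = c_out
        layers += [Conv1d(c_in, cfg.expansion_channels, cfg.kernel_size, rng), ReLU()]
        self.backbone = Sequential(*layers)
        self.global_max = GlobalMaxPool()
        self.dropout = Dropout(cfg.dropout_rate, np.random.default_rng(seed + 1))
        self.head = Linear(cfg.expansion_channels, cfg.n_classes, rng)

    def params(self) -> list[Param]:
        return self.backbone.params() + self.head.params()

    def features(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Pre-dropout feature vectors, shape (batch, expansion_channels)."""
        return self.global_max.forward(self.backbone.forward(x, training), training)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities, shape (batch, n_classes); rows sum to 1."""
        feats = self.dropout.forward(self.features(x, training), training)
        self._logits = self.head.forward(feats, training)
        return softmax(self._logits)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.dropout.backward(d)
        d = self.global_max.backward(d)
        self.backbone.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted class labels in {1, 2, 3, 4}."""
        return self.predict_proba(x).argmax(axis=1) + 1


class _ConvBlock(Layer):
    """[conv + (batchnorm) + ReLU] x 2."""

    def __init__(self, c_in: int, c_out: int, kernel: int, batch_norm: bool,
                 rng: np.random.Generator, first: bool = False):
        layers: list[Layer] = []
        for j, (cin, cout) in enumerate(((c_in, c_out), (c_out, c_out))):
            layers.append(Conv1d(cin, cout, kernel, rng,
                                 needs_input_grad=not (first and j == 0)))
            if batch_norm:
                layers.append(BatchNorm1d(cout))
            layers.append(ReLU())
        self.block = Sequential(*layers)

    def params(self) -> list[Param]:
        return self.block.params()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return self.block.forward(x, training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.block.backward(dout)


class UNetSegmenter(_Model):
    def __init__(self, config: SegmenterConfig | None = None, seed: int = 0):
        self.config = config or SegmenterConfig()
        self.seed = seed
        cfg = self.config
        rng = np.random.default_rng(seed)
        feats = cfg.encoder_features
        self.enc_blocks: list[_ConvBlock] = []
        self.pools: list[AvgPool1d] = []
        c_in = cfg.input_channels
        for i, f in enumerate(feats):
            self.enc_blocks.append(_ConvBlock(c_in, f, cfg.kernel_size, cfg.batch_norm,
                                              rng, first=i == 0))
            self.pools.append(AvgPool1d())
            c_in = f
        bottleneck_ch = feats[-1] * 2
        self.bottleneck = _ConvBlock(c_in, bottleneck_ch, cfg.kernel_size, cfg.batch_norm, rng)
        self.upsamples: list[UpsampleNearest] = []
        self.dec_blocks: list[_ConvBlock] = []
        c_in = bottleneck_ch
        for f in reversed(feats):
            self.upsamples.append(UpsampleNearest())
            self.dec_blocks.append(_ConvBlock(c_in + f, f, cfg.kernel_size, cfg.batch_norm, rng))
            c_in = f
        self.head = Conv1d(feats[0], 1, 1, rng)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for b in self.enc_blocks:
            out += b.params()
        out += self.bottleneck.params()
        for b in self.dec_blocks:
            out += b.params()
        out += self.head.params()
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Per-point region probabilities, shape (batch, input_length)."""
        skips: list[np.ndarray] = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = block.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        self._skip_channels = []
        for up, block, skip in zip(self.upsamples, self.dec_blocks, reversed(skips)):
            x = up.forward(x, training)
            self._skip_channels.append((x.shape[2], skip.shape[2]))
            x = np.concatenate([x, skip], axis=2)
            x = block.forward(x, training)
        logits = self.head.forward(x, training)[:, :, 0]
        return sigmoid(logits)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits[:, :, None])
        dskips: list[np.ndarray] = []
        for up, block, (c_up, c_skip) in zip(reversed(self.upsamples),
                                             reversed(self.dec_blocks),
                                             reversed(self._skip_channels)):
            d = block.backward(d)
            d, dskip = d[:, :, :c_up], d[:, :, c_up:]
            dskips.append(dskip)
            d = up.backward(d)
        d = self.bottleneck.backward(d)
        # dskips were collected shallowest-first; the encoder backward walks
        # deepest-first
        for block, pool, dskip in zip(reversed(self.enc_blocks), reversed(self.pools),
                                      reversed(dskips)):
            d = pool.backward(d)
            d = d + dskip
            d = block.backward(d)

    def predict_mask(self, x: np.ndarray, cutoff: float = 0.6) -> np.ndarray:
        """Binary masks after thresholding the probabilities at ``cutoff``."""
        return (self.forward(x, training=False) >= cutoff).astype(np.int8)

    # batch-norm running statistics belong to the checkpoint state
    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()] + _batchnorm_stats(self)

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.params()
        for p, s in zip(params, state[:len(params)], strict=False):
            p.value[...] = s
        bn_layers = _batchnorm_layers(self)
        bn_state = state[len(params):]
        for i, layer in enumerate(bn_layers):
            layer.running_mean = bn_state[2 * i].copy()
            layer.running_var = bn_state[2 * i + 1].copy()


def build_classifier(config: ClassifierConfig | None = None, seed: int = 0) -> PeakClassifier:
    return PeakClassifier(config, seed=seed)


def build_segmenter(config: SegmenterConfig | None = None, seed: int = 0) -> UNetSegmenter:
    return UNetSegmenter(config, seed=seed)


def classify(model: PeakClassifier, x: np.ndarray) -> np.ndarray:
    """Class probabilities for one 512x2 input or a batch of them."""
    x = _ensure_batch(x, model.config.input_length)
    return model.predict_proba(x)


def segment(model: UNetSegmenter, x: np.ndarray) -> np.ndarray:
    """Probability mask for one 512x2 input or a batch of them."""
    x = _ensure_batch(x, model.config.input_length)
    return model.forward(x, training=False)


def _ensure_batch(x: np.ndarray, length: int) -> np.ndarray:
    """Accept (length, 2) single inputs or batched (n, length, 2) inputs."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        if x.shape != (length, 2):
            raise ValueError(f"expected ({length}, 2) input, got {x.shape}")
        x = x[None]
    elif x.ndim != 3 or x.shape[1] != length or x.shape[2] != 2:
        raise ValueError(f"expected (n, {length}, 2) batch, got {x.shape}")
    return x


# ---------------------------------------------------------------------------
# checkpoints: one .npz of weights + a JSON sidecar with config and seed


def save_checkpoint(model: _Model, path: str | Path) -> None:
    path = Path(path)
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, **arrays)
    sidecar = {
        "model": type(model).__name__,
        "config": asdict(model.config),
        "seed": model.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> _Model:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if sidecar["model"] == "PeakClassifier":
        cfg = ClassifierConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in sidecar["config"].items()})
        model: _Model = PeakClassifier(cfg, seed=sidecar["seed"])
    elif sidecar["model"] == "UNetSegmenter":
        cfg = SegmenterConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in sidecar["config"].items()})
        model = UNetSegmenter(cfg, seed=sidecar["seed"])
    else:
        raise ValueError(f"unknown model type {sidecar['model']!r}")
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        model.set_state([data[f"p{i}"] for i in range(len(model.state_arrays()))])
    return model


def _batchnorm_layers(model: UNetSegmenter) -> list[BatchNorm1d]:
    blocks = model.enc_blocks + [model.bottleneck] + model.dec_blocks
    out = []
    for b in blocks:
        out += [l for l in b.block.layers if isinstance(l, BatchNorm1d)]
    return out


def _batchnorm_stats(model: UNetSegmenter) -> list[np.ndarray]:
    out = []
    for layer in _batchnorm_layers(model):
        out += [layer.running_mean, layer.running_var]
    return out


def copy_model(model: _Model) -> _Model:
    return copy.deepcopy(model)
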