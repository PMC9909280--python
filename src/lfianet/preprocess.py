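"""Two-channel preprocessing of raw scan traces.

The networks never see raw photodiode counts.  Each 512-point trace ``X`` is
background-subtracted (background = trace minimum) and expanded into two
unitless channels:

* channel 1, ``Y1 = (X - x_min) / (x_max - x_min)`` — min–max normalization,
  so the models learn peak shape rather than absolute intensity;
* channel 2, ``Y2 = log10(X - x_min + 1) / log10(x_max - x_min + 1)`` — a
  log-compressed view that lifts weak peaks toward the scale of strong ones.

The ``+1`` inside both logarithms removes the singularity of ``log10(0)`` at
the trace minimum while keeping the endpoint mapping exact (minimum -> 0,
maximum -> 1).

Constant traces carry no shape information and are rejected.
"""

from __future__ import annotations

import numpy as np

from .synthdata import TRACE_LENGTH


class DegenerateTraceError(ValueError):
    """Raised for constant traces, which have no peak information."""


def _validate(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (TRACE_LENGTH,):
        raise ValueError(f"expected a trace of length {TRACE_LENGTH}, got shape {x.shape}")
    if x.max() == x.min():
        raise DegenerateTraceError("constant trace: x_max == x_min")
    return x


def min_max_channel(x: np.ndarray) -> np.ndarray:
    """``Y1 = (X - x_min) / (x_max - x_min)``, in [0, 1]."""
    x = _validate(x)
    return (x - x.min()) / (x.max() - x.min())


def log_channel(x: np.ndarray) -> np.ndarray:
    """``Y2 = log10(X - x_min + 1) / log10(x_max - x_min + 1)``, in [0, 1].

    Evaluated via ``log1p`` so that traces with a tiny dynamic range stay
    finite (the base-10 factors cancel in the ratio).
    """
    x = _validate(x)
    return np.log1p(x - x.min()) / np.log1p(x.max() - x.min())


def to_model_input(x: np.ndarray) -> np.ndarray:
    """Column-stack both channels into the 512 x 2 network input."""
    return np.column_stack([min_max_channel(x), log_channel(x)])


def batch_model_input(traces: np.ndarray) -> np.ndarray:
    """Vectorized preprocessing of a (n, 512) array into (n, 512, 2) float32,
    the (batch, length, channels) layout the network layers use."""
    x = np.asarray(traces, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != TRACE_LENGTH:
        raise ValueError(f"expected (n, {TRACE_LENGTH}), got {x.shape}")
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    if np.any(hi == lo):
        raise DegenerateTraceError("batch contains a constant trace")
    y1 = (x - lo) / (hi - lo)
    y2 = np.log1p(x - lo) / np.log1p(hi - lo)
    return np.stack([y1, y2], axis=2).astype(np.float32)
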