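"""Minimal NumPy neural-network engine for the 1D models.

Implements exactly the layers the classifier and segmenter need — 1D
convolution (same padding), ReLU, max/average pooling, batch normalization,
nearest-neighbor upsampling, dropout, fully connected — with hand-written
backward passes, plus the Adam optimizer.  Everything is float32 and runs on
a single CPU through BLAS matmuls.

Tensor layout is ``(batch, length, channels)`` throughout: convolution with
kernel size k is then k shifted ``(B*L, C) @ (C, O)`` matmuls with no
transposition or im2col copies, which is what keeps a batch-8 training loop
viable in pure NumPy.

This is deliberately not a general autodiff system: layers cache what their
own backward pass needs and must be called forward-then-backward in matching
order.  Gradient correctness is checked against finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

#: compute dtype for the whole engine; float32 for speed.  Tests flip this to
#: float64 to run exact finite-difference gradient checks.
DTYPE = np.float32


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1D convolution; weight shape (kernel, in_ch, out_ch)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, needs_input_grad: bool = True):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        # the first layer of a network can skip propagating into the input
        self.needs_input_grad = needs_input_grad
        fan_in = in_channels * kernel_size
        # He initialization, appropriate for the ReLU nonlinearity
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(kernel_size, in_channels, out_channels))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_channels))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, length, c = x.shape
        k = self.kernel_size
        pad = k // 2
        xp = np.ascontiguousarray(np.pad(x, ((0, 0), (pad, pad), (0, 0)))) if pad else x
        w = self.weight.value
        out = np.empty((b, length, self.out_channels), dtype=x.dtype)
        np.copyto(out, self.bias.value)
        # one flat (B*Lp, C) @ (C, O) gemm per tap, then shifted accumulation;
        # slightly more flops than exact windows but BLAS-friendly at every
        # stage depth
        flat = xp.reshape(b * xp.shape[1], c)
        for t in range(k):
            y = (flat @ w[t]).reshape(b, xp.shape[1], self.out_channels)
            out += y[:, t:t + length, :]
        if training:
            self._xp = xp
            self._in_length = length
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._xp
        length = self._in_length
        b = dout.shape[0]
        k = self.kernel_size
        pad = k // 2
        w = self.weight.value
        for t in range(k):
            self.weight.grad[t] += np.tensordot(xp[:, t:t + length, :], dout,
                                                axes=([0, 1], [0, 1]))
        self.bias.grad += dout.sum(axis=(0, 1))
        self._xp = None
        if not self.needs_input_grad:
            return np.zeros((b, length, self.in_channels), dtype=DTYPE)
        dflat = dout.reshape(b * length, self.out_channels)
        dxp = np.zeros(xp.shape, dtype=DTYPE)
        for t in range(k):
            dxp[:, t:t + length, :] += (dflat @ w[t].T).reshape(b, length,
                                                               self.in_channels)
        return np.ascontiguousarray(dxp[:, pad:pad + length, :]) if pad else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling along the length axis, pool size 2."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, length, c = x.shape
        xr = x.reshape(b, length // 2, 2, c)
        idx = xr.argmax(axis=2)
        out = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
        if training:
            self._idx = idx
            self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, length, c = self._in_shape
        dxr = np.zeros((b, length // 2, 2, c), dtype=DTYPE)
        np.put_along_axis(dxr, self._idx[:, :, None, :], dout[:, :, None, :], axis=2)
        return dxr.reshape(b, length, c)


class AvgPool1d(Layer):
    """Non-overlapping average pooling along the length axis, pool size 2."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, length, c = x.shape
        self._in_shape = x.shape
        return x.reshape(b, length // 2, 2, c).mean(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, length, c = self._in_shape
        return np.repeat(dout * 0.5, 2, axis=1)


class UpsampleNearest(Layer):
    """Nearest-neighbor upsampling by a factor of 2 along the length axis."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return np.repeat(x, 2, axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, length, c = dout.shape
        return dout.reshape(b, length // 2, 2, c).sum(axis=2)


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * invstd
            self._xhat = xhat
            self._invstd = invstd
            return (self.gamma.value * xhat + self.beta.value).astype(DTYPE)
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean) * invstd
        return (self.gamma.value * xhat + self.beta.value).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        n = dout.shape[0] * dout.shape[1]
        dgamma = (dout * xhat).sum(axis=(0, 1))
        dbeta = dout.sum(axis=(0, 1))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        dx = (self.gamma.value * self._invstd / n) * (n * dout - dbeta - xhat * dgamma)
        self._xhat = None
        return dx.astype(DTYPE)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class GlobalMaxPool(Layer):
    """Max over the length axis: (b, l, c) -> (b, c)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        idx = x.argmax(axis=1)
        if training:
            self._idx = idx
            self._in_shape = x.shape
        return np.take_along_axis(x, idx[:, None, :], axis=1)[:, 0, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        np.put_along_axis(dx, self._idx[:, None, :], dout[:, None, :], axis=1)
        return dx


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_features))

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ dout
        self.bias.grad += dout.sum(axis=0)
        self._x = None
        return dout @ self.weight.value.T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


try:  # fused single-pass update; the big conv layers make Adam memory-bound
    import numba

    @numba.njit(fastmath=True)
    def _adam_kernel(p, g, m, v, lr, b1, b2, eps, b1t, b2t):  # pragma: no cover
        for i in range(p.size):
            m[i] = b1 * m[i] + (1.0 - b1) * g[i]
            v[i] = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
            p[i] -= lr * (m[i] / b1t) / (np.sqrt(v[i] / b2t) + eps)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class Adam:
    """Adam with the standard defaults (betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, params: list[Param], lr: float = 0.001,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if _HAVE_NUMBA and p.value.dtype == np.float32:
                _adam_kernel(p.value.ravel(), p.grad.ravel(), m.ravel(), v.ravel(),
                             self.lr, self.b1, self.b2, self.eps, b1t, b2t)
            else:
                m *= self.b1
                m += (1 - self.b1) * p.grad
                v *= self.b2
                v += (1 - self.b2) * np.square(p.grad)
                p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
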