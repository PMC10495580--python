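"""Minimal 1D convolutional network engine in NumPy.

Implements exactly what the QC classifiers need: 1D convolution (same
padding), ReLU, max pooling, inception blocks (parallel kernel-size-1/3/5
branches plus a pooled branch, channel-concatenated), dense layers, a
softmax / categorical cross-entropy head, and the Adam optimizer.  Forward
and backward passes are vectorized through an im2col reshaping so the heavy
lifting is BLAS matrix multiplication; backward also propagates gradients to
the *input*, which integrated-gradients attribution relies on.

Arrays are float32 with layout (batch, channels, length).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1d",
    "ReLU",
    "MaxPool1d",
    "Flatten",
    "Dense",
    "Inception1d",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def _f32(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x, dtype=np.float32)


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) pairs."""
        return []


class Conv1d(Layer):
    """1D convolution with stride 1 and zero same-padding (odd kernel)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * kernel
        self.W = _f32(rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel)))
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)  # (n,c,L,k)
        return win.transpose(0, 2, 1, 3).reshape(n * length, c * self.kernel)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        cols = _f32(self._im2col(x))
        self._cols = cols
        self._shape = x.shape
        w2 = self.W.reshape(self.out_channels, -1)
        out = cols @ w2.T + self.b
        return out.reshape(n, length, self.out_channels).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        dy2 = _f32(dy.transpose(0, 2, 1).reshape(n * length, self.out_channels))
        self.dW[...] = (dy2.T @ self._cols).reshape(self.W.shape)
        self.db[...] = dy2.sum(axis=0)
        dcols = (dy2 @ self.W.reshape(self.out_channels, -1)).reshape(n, length, c, self.kernel)
        dcols = dcols.transpose(0, 2, 1, 3)  # (n, c, L, k)
        p = self.kernel // 2
        dxp = np.zeros((n, c, length + 2 * p), dtype=np.float32)
        for i in range(self.kernel):
            dxp[:, :, i : i + length] += dcols[:, :, :, i]
        return dxp[:, :, p : p + length]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0)


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing remainder window is dropped."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        lo = length // self.pool
        self._in_len = length
        xv = x[:, :, : lo * self.pool].reshape(n, c, lo, self.pool)
        self._argmax = xv.argmax(axis=3)
        return xv.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, lo = dy.shape
        dxv = np.zeros((n, c, lo, self.pool), dtype=np.float32)
        np.put_along_axis(dxv, self._argmax[..., None], _f32(dy)[..., None], axis=3)
        dx = np.zeros((n, c, self._in_len), dtype=np.float32)
        dx[:, :, : lo * self.pool] = dxv.reshape(n, c, lo * self.pool)
        return dx


class _SamePool3(Layer):
    """Stride-1 max pooling of width 3 with same padding (inception pooled branch)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1)), constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, 3, axis=2)  # (n,c,L,3)
        self._argmax = win.argmax(axis=3)
        self._shape = x.shape
        return win.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        dxp = np.zeros((n, c, length + 2), dtype=np.float32)
        # window j covers padded positions j..j+2; argmax gives the offset
        pos = self._argmax + np.arange(length)[None, None, :]
        np.add.at(dxp, (np.arange(n)[:, None, None], np.arange(c)[None, :, None], pos), _f32(dy))
        return dxp[:, :, 1:-1]


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = _f32(rng.normal(0.0, np.sqrt(2.0 / in_features), (in_features, out_features)))
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = _f32(x)
        return self._x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = _f32(dy)
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Inception1d(Layer):
    """Inception block: parallel conv branches of kernel 1/3/5 plus a pooled
    1x1-conv branch, channel-concatenated (output = 4 * branch_channels)."""

    def __init__(self, in_channels: int, branch_channels: int, rng: np.random.Generator):
        self.branch_channels = branch_channels
        self.conv1 = Conv1d(in_channels, branch_channels, 1, rng)
        self.conv3 = Conv1d(in_channels, branch_channels, 3, rng)
        self.conv5 = Conv1d(in_channels, branch_channels, 5, rng)
        self.pool = _SamePool3()
        self.convp = Conv1d(in_channels, branch_channels, 1, rng)
        self.relu = [ReLU() for _ in range(4)]

    @property
    def out_channels(self) -> int:
        return 4 * self.branch_channels

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = [
            self.relu[0].forward(self.conv1.forward(x)),
            self.relu[1].forward(self.conv3.forward(x)),
            self.relu[2].forward(self.conv5.forward(x)),
            self.relu[3].forward(self.convp.forward(self.pool.forward(x))),
        ]
        return np.concatenate(outs, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c = self.branch_channels
        parts = [dy[:, i * c : (i + 1) * c, :] for i in range(4)]
        dx = self.conv1.backward(self.relu[0].backward(parts[0]))
        dx = dx + self.conv3.backward(self.relu[1].backward(parts[1]))
        dx = dx + self.conv5.backward(self.relu[2].backward(parts[2]))
        dx = dx + self.pool.backward(self.convp.backward(self.relu[3].backward(parts[3])))
        return dx

    def params(self):
        return self.conv1.params() + self.conv3.params() + self.conv5.params() + self.convp.params()


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward_until(self, x: np.ndarray, stop: int) -> np.ndarray:
        """Forward through layers[:stop] only (penultimate feature extraction)."""
        for layer in self.layers[:stop]:
            x = layer.forward(x)
        return x

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError("state length mismatch")
        for (p, _), a in zip(params, arrays):
            p[...] = a


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and gradient w.r.t. logits.

    ``y`` holds integer class indices.
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-12)))
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    return loss, _f32(dlogits / n)


class Adam:
    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
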