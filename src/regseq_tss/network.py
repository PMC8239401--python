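"""Minimal convolutional network engine for one-hot DNA sequence input.

Implements exactly the layer vocabulary the constrained architecture family
needs — same-padded 1-D convolution, ReLU, inverted dropout, non-overlapping
max pooling, dense layers, a single sigmoid output — together with reverse-mode
gradients for both the parameters (training) and the input (saliency maps),
and an Adam optimizer with per-step learning-rate decay.

All computation is plain numpy. Convolutions are evaluated as im2col matrix
products, which keeps a 40-epoch training run on a few thousand 500-bp
windows within minutes on one CPU core. Given a fixed integer seed the whole
stack is bit-reproducible: weight initialization, dropout masks and batch
shuffling all draw from a single ``numpy.random.Generator``.

Arrays are ``(batch, length, channels)``; the default dtype is float32
(float64 is available for gradient checking).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "Dense",
    "Dropout",
    "MaxPool1D",
    "ReLU",
    "Flatten",
    "Network",
    "Adam",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable two-branch form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer: forward caches what backward needs; params/grads exposed."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                    shape: tuple[int, ...], dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv1D(Layer):
    """Stride-1 cross-correlation, zero-padded to preserve length.

    Filter size must be odd so same-padding is symmetric (the architecture
    family only uses 5/9/19/29).
    """

    def __init__(self, in_channels: int, n_filters: int, filter_size: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        if filter_size % 2 == 0:
            raise ValueError("filter_size must be odd for symmetric padding")
        self.in_channels = in_channels
        self.n_filters = n_filters
        self.filter_size = filter_size
        self.pad = filter_size // 2
        fan_in = filter_size * in_channels
        self.W = _glorot_uniform(rng, fan_in, n_filters,
                                 (fan_in, n_filters), dtype)
        self.b = np.zeros(n_filters, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        # (B, L, C, k) -> (B, L, k, C) -> (B, L, k*C)
        cols = np.lib.stride_tricks.sliding_window_view(
            xp, self.filter_size, axis=1
        )
        return np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(
            B, L, self.filter_size * C
        )

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._in_shape = x.shape
        self._cols = self._im2col(x)
        return self._cols @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, C = self._in_shape
        k = self.filter_size
        self.grads[0][...] = np.tensordot(self._cols, dy, axes=([0, 1], [0, 1]))
        self.grads[1][...] = dy.sum(axis=(0, 1))
        dcols = (dy @ self.W.T).reshape(B, L, k, C)
        dxp = np.zeros((B, L + 2 * self.pad, C), dtype=dy.dtype)
        for j in range(k):  # fold overlapping windows back (col2im)
            dxp[:, j : j + L, :] += dcols[:, :, j, :]
        return dxp[:, self.pad : self.pad + L, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout: active only during training, identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; window equals stride, length must divide."""

    def __init__(self, window: int) -> None:
        super().__init__()
        self.window = window

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, F = x.shape
        if L % self.window:
            raise ValueError(f"length {L} not divisible by pool window {self.window}")
        r = x.reshape(B, L // self.window, self.window, F)
        self._argmax = r.argmax(axis=2)
        self._in_shape = x.shape
        return np.take_along_axis(r, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, F = self._in_shape
        dr = np.zeros((B, L // self.window, self.window, F), dtype=dy.dtype)
        np.put_along_axis(dr, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        return dr.reshape(B, L, F)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.W = _glorot_uniform(rng, in_features, out_features,
                                 (in_features, out_features), dtype)
        self.b = np.zeros(out_features, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class Network:
    """A feed-forward stack ending in a single pre-sigmoid output unit.

    ``score`` returns the logit S(X) (the quantity the saliency map
    differentiates); ``predict_proba`` applies the sigmoid.
    """

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def score(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x[:, 0]

    def predict_proba(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return sigmoid(self.score(x, train=train))

    def backward(self, dscore: np.ndarray) -> np.ndarray:
        """Backpropagate d(objective)/d(score); returns d(objective)/d(input)."""
        dy = dscore[:, None]
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """Gradient of the pre-sigmoid score w.r.t. the input, inference mode."""
        self.score(x, train=False)
        return self.backward(np.ones(x.shape[0], dtype=x.dtype))

    # -- persistence ------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p for i, p in enumerate(self.params)}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params):
            src = arrays[f"param_{i}"]
            if src.shape != p.shape:
                raise ValueError(
                    f"param {i}: shape {src.shape} does not match {p.shape}"
                )
            p[...] = src


class Adam:
    """Adam with the per-step decayed learning rate lr_t = lr / (1 + decay*t)."""

    def __init__(self, params: list[np.ndarray], lr: float = 3e-4,
                 decay: float = 1e-6, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.decay = decay
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        lr_t = self.lr / (1.0 + self.decay * self.t)
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g, dtype=np.float64)
            update = lr_t * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
            p -= update.astype(p.dtype)
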