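"""Minimal NumPy neural-network engine used by the classifier.

Implements exactly the layer set the architecture needs — 1-D convolution
(same padding, stride 1), batch normalization, PReLU, max-pooling,
bidirectional LSTM, dense, dropout — with hand-written backward passes and an
Adam optimizer.  Everything is float64 and deterministic given the seed; no
external deep-learning framework is required.

Data layout: batches are channels-last, (N, L, C) for temporal layers and
(N, D) after the recurrent reduction.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

__all__ = [
    "Conv1D", "BatchNorm", "PReLU", "MaxPool1D", "BiLSTM", "Dense", "Dropout",
    "Sequential", "softmax", "softmax_cross_entropy", "Adam",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    """Base layer: subclasses fill ``params``/``grads`` with aligned arrays."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv1D(Layer):
    """1-D convolution, stride 1, 'same' zero padding.

    Computed as a sum of k tap-shifted matmuls, which avoids im2col copies.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.w = _glorot(rng, kernel * c_in, c_out, (kernel, c_in, c_out))
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.pad_l = (kernel - 1) // 2
        self.pad_r = kernel // 2

    def forward(self, x, training=False):
        n, length, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_l, self.pad_r), (0, 0)))
        self._xp, self._in_len = xp, length
        y = np.empty((n, length, self.c_out), dtype=DTYPE)
        y[...] = self.b
        for j in range(self.kernel):
            y += xp[:, j : j + length, :] @ self.w[j]
        return y

    def backward(self, dy):
        n, length, _ = dy.shape
        xp = self._xp
        self.grads[1][...] = dy.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        for j in range(self.kernel):
            self.grads[0][j] = np.tensordot(
                xp[:, j : j + length, :], dy, axes=([0, 1], [0, 1])
            )
            dxp[:, j : j + length, :] += dy @ self.w[j].T
        return dxp[:, self.pad_l : self.pad_l + length, :]


class BatchNorm(Layer):
    """Normalizes the trailing channel axis over all leading axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._m = x.size // x.shape[-1]
        else:
            mean, var = self.running_mean, self.running_var
        self._xhat = (x - mean) / np.sqrt(var + self.eps)
        self._std = np.sqrt(var + self.eps)
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.grads[0][...] = (dy * self._xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        if not self._training:
            return dy * self.gamma / self._std
        m = self._m
        dxhat = dy * self.gamma
        return (
            dxhat - dxhat.mean(axis=axes) - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) / self._std


class PReLU(Layer):
    """Parametric ReLU with one learned slope per channel."""

    def __init__(self, channels: int, init: float = 0.25):
        super().__init__()
        self.alpha = np.full(channels, init, dtype=DTYPE)
        self.params = [self.alpha]
        self.grads = [np.zeros_like(self.alpha)]

    def forward(self, x, training=False):
        self._x = x
        return np.where(x > 0, x, self.alpha * x)

    def backward(self, dy):
        x = self._x
        neg = x <= 0
        axes = tuple(range(x.ndim - 1))
        self.grads[0][...] = (dy * x * neg).sum(axis=axes)
        return np.where(neg, self.alpha * dy, dy)


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling; odd trailing samples are dropped."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, training=False):
        n, length, c = x.shape
        lo = length // self.size
        xr = x[:, : lo * self.size, :].reshape(n, lo, self.size, c)
        self._argmax = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dy):
        n, lo, c = dy.shape
        dxr = np.zeros((n, lo, self.size, c))
        np.put_along_axis(dxr, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape)
        dx[:, : lo * self.size, :] = dxr.reshape(n, lo * self.size, c)
        return dx


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _LSTMDirection:
    """One direction of an LSTM; returns the final hidden state."""

    def __init__(self, c_in: int, units: int, rng: np.random.Generator):
        h = units
        self.units = h
        self.wx = _glorot(rng, c_in, 4 * h, (c_in, 4 * h))
        self.wh = _glorot(rng, h, 4 * h, (h, 4 * h))
        self.b = np.zeros(4 * h, dtype=DTYPE)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        self.grads = [np.zeros_like(self.wx), np.zeros_like(self.wh), np.zeros_like(self.b)]

    @property
    def params(self):
        return [self.wx, self.wh, self.b]

    def forward(self, x):
        n, t_len, _ = x.shape
        h = self.units
        hs = np.zeros((n, h))
        cs = np.zeros((n, h))
        self._cache = []
        self._x = x
        for t in range(t_len):
            xt = x[:, t, :]
            a = xt @ self.wx + hs @ self.wh + self.b
            i = _sigmoid(a[:, :h])
            f = _sigmoid(a[:, h : 2 * h])
            g = np.tanh(a[:, 2 * h : 3 * h])
            o = _sigmoid(a[:, 3 * h :])
            c_prev, h_prev = cs, hs
            cs = f * c_prev + i * g
            tc = np.tanh(cs)
            hs = o * tc
            self._cache.append((xt, h_prev, c_prev, i, f, g, o, tc))
        return hs

    def backward(self, dh_final):
        x = self._x
        n, t_len, c_in = x.shape
        h = self.units
        for gr in self.grads:
            gr[...] = 0.0
        dx = np.zeros_like(x)
        dh = dh_final.copy()
        dc = np.zeros((n, h))
        for t in range(t_len - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc = dc * f
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            self.grads[0] += xt.T @ da
            self.grads[1] += h_prev.T @ da
            self.grads[2] += da.sum(axis=0)
            dx[:, t, :] = da @ self.wx.T
            dh = da @ self.wh.T
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM over (N, T, C); emits concatenated final states (N, 2*units)."""

    def __init__(self, c_in: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = _LSTMDirection(c_in, units, rng)
        self.bwd = _LSTMDirection(c_in, units, rng)
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads

    def forward(self, x, training=False):
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1, :])
        return np.concatenate([hf, hb], axis=1)

    def backward(self, dy):
        h = self.fwd.units
        dxf = self.fwd.backward(dy[:, :h])
        dxb = self.bwd.backward(dy[:, h:])
        return dxf + dxb[:, ::-1, :]


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = _glorot(rng, d_in, d_out, (d_in, d_out))
        self.b = np.zeros(d_out, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        if len(weights) != len(self.params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(self.params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w

    def get_state(self) -> list[np.ndarray]:
        """Trainable parameters plus batch-norm running statistics."""
        state = self.get_weights()
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        n = len(self.params)
        self.set_weights(state[:n])
        extra = state[n:]
        i = 0
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = extra[i]
                layer.running_var[...] = extra[i + 1]
                i += 2
        if i != len(extra):
            raise ValueError("state list length mismatch")


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Returns (mean loss, probabilities, gradient w.r.t. logits)."""
    probs = softmax(logits)
    eps = 1e-12
    loss = -np.sum(onehot * np.log(probs + eps)) / len(logits)
    grad = (probs - onehot) / len(logits)
    return float(loss), probs, grad


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
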