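"""A compact NumPy implementation of the 1-D convolutional building blocks.

This module provides exactly the layers the classifier needs — Conv1D with
"same" padding, ELU, group normalization, "same"-padded max pooling, inverted
dropout, flatten and dense — each with a hand-written backward pass, plus a
``Network`` container that exposes parameter gradients (for SGD training) and
input gradients (for saliency attribution). All randomness flows through an
explicit ``numpy.random.Generator``.

Shapes follow the channels-last convention: a batch is (B, positions, channels).
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-5


def elu(x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    return np.where(x > 0, x, alpha * np.expm1(np.minimum(x, 0.0)))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_from_logits(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy, computed stably from pre-sigmoid scores."""
    # softplus(z) - y*z = -[y log p + (1-y) log(1-p)]
    sp = np.logaddexp(0.0, logits)
    return float(np.mean(sp - y * logits))


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: stateless unless it holds parameters."""

    #: L2 coefficient applied to this layer's weights AND biases (0 = none)
    l2 = 0.0

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_length(self, length: int) -> int:
        return length


class Conv1D(Layer):
    """1-D convolution, stride ``s``, zero "same" padding, optional L2."""

    def __init__(self, c_in: int, filters: int, kernel_size: int, stride: int = 1,
                 l2: float = 0.0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.k, self.s = kernel_size, stride
        self.W = glorot_uniform(rng, (kernel_size * c_in, filters),
                                fan_in=kernel_size * c_in, fan_out=filters)
        self.b = np.zeros(filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.l2 = l2

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def out_length(self, length: int) -> int:
        return -(-length // self.s)  # ceil, "same" padding

    def _pad(self, length: int) -> tuple[int, int]:
        out = self.out_length(length)
        total = max((out - 1) * self.s + self.k - length, 0)
        left = total // 2
        return left, total - left

    def forward(self, x, train, rng):
        B, L, C = x.shape
        left, right = self._pad(L)
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        out_len = self.out_length(L)
        # im2col: (B, out_len, k*C)
        starts = np.arange(out_len) * self.s
        cols = np.stack([xp[:, starts + j, :] for j in range(self.k)], axis=2)
        self._cols = cols.reshape(B, out_len, self.k * C)
        self._in_shape = (B, L, C)
        return self._cols @ self.W + self.b

    def backward(self, dy):
        B, L, C = self._in_shape
        out_len = dy.shape[1]
        flat_cols = self._cols.reshape(-1, self.k * C)
        self.dW[...] = flat_cols.T @ dy.reshape(-1, self.W.shape[1])
        self.db[...] = dy.sum(axis=(0, 1))
        dcols = (dy @ self.W.T).reshape(B, out_len, self.k, C)
        left, right = self._pad(L)
        dxp = np.zeros((B, L + left + right, C))
        starts = np.arange(out_len) * self.s
        for j in range(self.k):
            np.add.at(dxp, (slice(None), starts + j, slice(None)), dcols[:, :, j, :])
        return dxp[:, left : left + L, :]


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, train, rng):
        self._y = elu(x, self.alpha)
        self._pos = x > 0
        return self._y

    def backward(self, dy):
        return dy * np.where(self._pos, 1.0, self._y + self.alpha)


class GroupNorm(Layer):
    """Normalize each sample within fixed-size channel groups (over positions
    and the group's channels), then apply a learned per-channel affine."""

    def __init__(self, channels: int, groups: int):
        if channels % groups:
            raise ValueError(f"channels ({channels}) must be divisible by groups ({groups})")
        self.g = groups
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train, rng):
        B, L, C = x.shape
        xg = x.reshape(B, L, self.g, C // self.g)
        mu = xg.mean(axis=(1, 3), keepdims=True)
        var = xg.var(axis=(1, 3), keepdims=True)
        self._istd = 1.0 / np.sqrt(var + _EPS)
        self._xhat = (xg - mu) * self._istd
        self._shape = (B, L, C)
        return self._xhat.reshape(B, L, C) * self.gamma + self.beta

    def backward(self, dy):
        B, L, C = self._shape
        self.dgamma[...] = (dy * self._xhat.reshape(B, L, C)).sum(axis=(0, 1))
        self.dbeta[...] = dy.sum(axis=(0, 1))
        dxhat = (dy * self.gamma).reshape(B, L, self.g, C // self.g)
        m = L * (C // self.g)
        # standard normalization backward, per (sample, group)
        sum_d = dxhat.sum(axis=(1, 3), keepdims=True)
        sum_dx = (dxhat * self._xhat).sum(axis=(1, 3), keepdims=True)
        dxg = (self._istd / m) * (m * dxhat - sum_d - self._xhat * sum_dx)
        return dxg.reshape(B, L, C)


class MaxPool1D(Layer):
    """Max pooling with "same" padding: output length = ceil(L / stride)."""

    def __init__(self, pool_size: int, stride: int):
        self.l, self.r = pool_size, stride

    def out_length(self, length: int) -> int:
        return -(-length // self.r)

    def forward(self, x, train, rng):
        B, L, C = x.shape
        out_len = self.out_length(L)
        total = max((out_len - 1) * self.r + self.l - L, 0)
        left = total // 2
        xp = np.full((B, L + total, C), -np.inf)
        xp[:, left : left + L, :] = x
        starts = np.arange(out_len) * self.r
        windows = np.stack([xp[:, starts + j, :] for j in range(self.l)], axis=2)
        self._arg = windows.argmax(axis=2)
        self._meta = (B, L, C, left, total, starts)
        return windows.max(axis=2)

    def backward(self, dy):
        B, L, C, left, total, starts = self._meta
        dxp = np.zeros((B, L + total, C))
        b_idx, o_idx, c_idx = np.meshgrid(
            np.arange(B), np.arange(len(starts)), np.arange(C), indexing="ij"
        )
        pos = starts[o_idx] + self._arg
        np.add.at(dxp, (b_idx, pos, c_idx), dy)
        return dxp[:, left : left + L, :]


class Dropout(Layer):
    """Inverted dropout: active only during training, identity at inference."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, l2: float = 0.0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = glorot_uniform(rng, (n_in, n_out), fan_in=n_in, fan_out=n_out)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.l2 = l2

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Network:
    """An ordered stack of layers ending in a single pre-sigmoid output unit."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x[:, 0]  # logits

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dy = dlogits[:, None]
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(x, train=False))

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(logit)/d(input), evaluated in inference mode (dropout off)."""
        logits = self.forward(x, train=False)
        return self.backward(np.ones_like(logits))

    def l2_loss(self) -> float:
        return float(sum(layer.l2 * sum(np.sum(p**2) for p in layer.params())
                         for layer in self.layers if layer.l2))

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        """Regularized mean BCE in inference mode (used for validation)."""
        return bce_from_logits(self.forward(x, train=False), y) + self.l2_loss()

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params():
                p[...] = weights[i]
                i += 1
        if i != len(weights):
            raise ValueError(f"weight count mismatch: expected {i}, got {len(weights)}")

    def n_params(self) -> int:
        return int(sum(p.size for layer in self.layers for p in layer.params()))

    def train_step(self, x: np.ndarray, y: np.ndarray,
                   optimizer: "SGDMomentum", rng: np.random.Generator) -> float:
        """One mini-batch update; returns the batch's regularized loss."""
        logits = self.forward(x, train=True, rng=rng)
        loss = bce_from_logits(logits, y) + self.l2_loss()
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss ({loss}); "
                                     "try a smaller learning rate")
        p = sigmoid(logits)
        self.backward((p - y) / len(y))
        for layer in self.layers:
            if layer.l2:
                for param, grad in zip(layer.params(), layer.grads()):
                    grad += 2.0 * layer.l2 * param
        optimizer.step(self)
        return loss


class SGDMomentum:
    """Stochastic gradient descent with classical momentum:
    v <- momentum * v - lr * grad;  w <- w + v."""

    def __init__(self, learning_rate: float = 0.005, momentum: float = 0.95):
        self.lr = learning_rate
        self.momentum = momentum
        self._velocity: dict[int, list[np.ndarray]] = {}

    def step(self, net: Network) -> None:
        for li, layer in enumerate(net.layers):
            params, grads = layer.params(), layer.grads()
            if not params:
                continue
            vel = self._velocity.setdefault(li, [np.zeros_like(p) for p in params])
            for p, g, v in zip(params, grads, vel):
                v *= self.momentum
                v -= self.lr * g
                p += v
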