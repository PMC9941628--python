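"""Minimal numpy deep-learning engine for the residual image classifier.

Implements only what the 32-layer residual network needs: 2-D convolution
(im2col + GEMM), batch normalization, ReLU, 2x2 max pooling, global
average pooling, a fully connected head, softmax cross-entropy, and SGD
with momentum and weight decay.  Everything runs in float32, is driven by
explicit `numpy.random.Generator` seeds, and is deterministic.

Layers expose ``forward(x, train)`` / ``backward(dout)`` and publish
their parameters as :class:`Param` objects (value + gradient), which the
optimizer updates in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2x2",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "ResidualBlock",
    "softmax",
    "cross_entropy",
    "SGD",
]


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)
    decay: bool = True  # weight decay applies (off for BN scale/shift, biases)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * k * k, oh * ow), (n, c, h, w, oh, ow)


def _col2im(cols: np.ndarray, shape, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w, oh, ow = shape
    cols = cols.reshape(n, c, k, k, oh, ow)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


class Conv2d(Layer):
    """k x k convolution, He-initialized, no bias (a BN layer follows).

    ``projection`` marks 1x1 shortcut convolutions, which by the usual
    residual-network convention are excluded from the weighted-layer count.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int = 3,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        projection: bool = False,
    ):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.projection = projection
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = Param(
            rng.normal(0.0, scale, size=(c_out, c_in * k * k)).astype(np.float32)
        )
        self._cache = None

    def params(self):
        return [self.w]

    def forward(self, x, train):
        cols, shape = _im2col(x, self.k, self.stride, self.pad)
        n, _, L = cols.shape
        flat = cols.transpose(1, 0, 2).reshape(cols.shape[1], n * L)
        out = self.w.value @ flat  # (c_out, n*L)
        oh, ow = shape[4], shape[5]
        self._cache = (flat, shape)
        return out.reshape(-1, n, L).transpose(1, 0, 2).reshape(n, -1, oh, ow)

    def backward(self, dout):
        flat, shape = self._cache
        n, c, h, w, oh, ow = shape
        dflat_out = dout.reshape(n, -1, oh * ow).transpose(1, 0, 2).reshape(
            dout.shape[1], n * oh * ow
        )
        self.w.grad[...] = dflat_out @ flat.T
        dcols = (self.w.value.T @ dflat_out).reshape(-1, n, oh * ow).transpose(1, 0, 2)
        return _col2im(dcols, shape, self.k, self.stride, self.pad)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32), )
        self.gamma.decay = False
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.beta.decay = False
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean += self.momentum * (mean - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, dout):
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad[...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad[...] = dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] * inv[None, :, None, None]
        term = (
            dout
            - dout.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dout * xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        return g * term


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2x2(Layer):
    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        # split gradient across ties so pooling stays gradient-exact
        self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        self._shape = x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        d = self._mask * dout[:, :, :, None, :, None]
        return d.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / (h * w)


class Linear(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / c_in)
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in)).astype(np.float32))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self.b.decay = False

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout):
        self.w.grad[...] = dout.T @ self._x
        self.b.grad[...] = dout.sum(axis=0)
        return dout @ self.w.value


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class ResidualBlock(Layer):
    """conv-BN-ReLU-conv-BN on the main path, plus shortcut, then ReLU.

    With ``c_in == c_out`` and stride 1 the shortcut is the identity
    ("identity block"); otherwise it is a 1x1 projection convolution with
    its own BN ("conv block").
    """

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        self.main = Sequential(
            Conv2d(c_in, c_out, 3, stride=stride, rng=rng),
            BatchNorm2d(c_out),
            ReLU(),
            Conv2d(c_out, c_out, 3, rng=rng),
            BatchNorm2d(c_out),
        )
        self.is_identity = c_in == c_out and stride == 1
        if not self.is_identity:
            self.short = Sequential(
                Conv2d(c_in, c_out, 1, stride=stride, pad=0, rng=rng, projection=True),
                BatchNorm2d(c_out),
            )
        self.relu = ReLU()

    def params(self):
        ps = self.main.params()
        if not self.is_identity:
            ps += self.short.params()
        return ps

    def forward(self, x, train):
        main = self.main.forward(x, train)
        short = x if self.is_identity else self.short.forward(x, train)
        if main.shape != short.shape:
            raise ValueError(
                f"residual shape mismatch: main {main.shape} vs shortcut {short.shape}"
            )
        return self.relu.forward(main + short, train)

    def backward(self, dout):
        d = self.relu.backward(dout)
        dmain = self.main.backward(d)
        dshort = d if self.is_identity else self.short.backward(d)
        return dmain + dshort


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -float(logp[np.arange(n), labels].mean())
    grad = softmax(logits)
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class SGD:
    """SGD with classical momentum and decoupled-from-BN weight decay."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 0.01,
        momentum: float = 0.9,
        weight_decay: float = 1e-4,
    ):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.vel = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.vel):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v -= self.lr * g
            p.value += v
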