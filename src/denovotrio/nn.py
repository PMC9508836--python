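"""Minimal CNN engine on numpy: layers, manual backprop, Adam/AdamW.

Supports exactly what the pileup-image classifier needs: 3x3 same-padding
stride-1 convolutions (computed as nine shifted channel matmuls through
BLAS), ReLU, per-channel batch normalization with running statistics,
squeeze-and-excitation channel gating, a global max+average pooling head,
a dense sigmoid output with optional L1 penalty, binary cross-entropy,
and the Adam / AdamW (decoupled weight decay) optimizers.

Tensors are NHWC float32.  Every layer implements ``forward(x, train)``
and ``backward(dy)``; parameters carry their own gradients.  Weight
initialisation is He-normal from a caller-supplied seeded generator, so
two builds from the same seed are bit-identical.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ReLU",
    "BatchNorm",
    "SqueezeExcite",
    "GlobalPoolConcat",
    "Dense",
    "Sequential",
    "Adam",
    "bce_loss_and_grad",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or kxk) stride-1 same-padding convolution, NHWC."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.kernel = kernel
        self.w = Param(rng.normal(0.0, scale, size=(kernel, kernel, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self._xp: Optional[np.ndarray] = None

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.kernel
        pad = k // 2
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        y = np.broadcast_to(self.b.value, (n, h, w, self.b.value.shape[0])).copy()
        for di in range(k):
            for dj in range(k):
                y += xp[:, di:di + h, dj:dj + w, :] @ self.w.value[di, dj]
        self._xp = xp if train else None
        self._shape = (n, h, w)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.kernel
        n, h, w = self._shape
        xp = self._xp
        assert xp is not None
        self.b.grad += dy.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                patch = xp[:, di:di + h, dj:dj + w, :]
                self.w.grad[di, dj] += np.tensordot(
                    patch, dy, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, di:di + h, dj:dj + w, :] += dy @ self.w.value[di, dj].T
        pad = k // 2
        self._xp = None
        return dxp[:, pad:pad + h, pad:pad + w, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(np.float32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        if train:
            self._cache = (xhat, invstd, x.shape[0] * x.shape[1] * x.shape[2])
        return xhat * self.gamma.value + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, m = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma.value
        sum_dxhat = dxhat.sum(axis=(0, 1, 2))
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 1, 2))
        return (invstd / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class SqueezeExcite(Layer):
    """Channel attention: global average -> bottleneck -> sigmoid gates."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        hidden = max(1, channels // reduction)
        self.w1 = Param(rng.normal(0.0, np.sqrt(2.0 / channels),
                                   size=(channels, hidden)))
        self.b1 = Param(np.zeros(hidden))
        self.w2 = Param(rng.normal(0.0, np.sqrt(2.0 / hidden),
                                   size=(hidden, channels)))
        self.b2 = Param(np.zeros(channels))

    def params(self) -> List[Param]:
        return [self.w1, self.b1, self.w2, self.b2]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        s = x.mean(axis=(1, 2))  # squeeze (N, C)
        z1 = s @ self.w1.value + self.b1.value
        h = np.maximum(z1, 0.0)
        g = sigmoid(h @ self.w2.value + self.b2.value)
        self._cache = (x, s, z1, h, g)
        return x * g[:, None, None, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s, z1, h, g = self._cache
        n, hh, ww, _ = x.shape
        dx = dy * self._cache[4][:, None, None, :]
        dg = (dy * x).sum(axis=(1, 2))
        dz2 = dg * g * (1.0 - g)
        self.w2.grad += h.T @ dz2
        self.b2.grad += dz2.sum(axis=0)
        dh = dz2 @ self.w2.value.T
        dz1 = dh * (z1 > 0)
        self.w1.grad += s.T @ dz1
        self.b1.grad += dz1.sum(axis=0)
        ds = dz1 @ self.w1.value.T
        dx += ds[:, None, None, :] / (hh * ww)
        return dx


class GlobalPoolConcat(Layer):
    """Concatenate global max pooling and global average pooling -> (N, 2C)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        flat = x.reshape(n, h * w, c)
        self._argmax = flat.argmax(axis=1)  # (N, C)
        mx = np.take_along_axis(flat, self._argmax[:, None, :], axis=1)[:, 0, :]
        avg = flat.mean(axis=1)
        self._shape = (n, h, w, c)
        return np.concatenate([mx, avg], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dmx, davg = dy[:, :c], dy[:, c:]
        dflat = np.repeat(davg[:, None, :] / (h * w), h * w, axis=1)
        np.put_along_axis(
            dflat, self._argmax[:, None, :],
            np.take_along_axis(dflat, self._argmax[:, None, :], axis=1) + dmx[:, None, :],
            axis=1,
        )
        return dflat.reshape(n, h, w, c)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 l1: float = 0.0):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self.l1 = l1

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        if self.l1 > 0.0:
            self.w.grad += self.l1 * np.sign(self.w.value)
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T

    def l1_penalty(self) -> float:
        return float(self.l1 * np.abs(self.w.value).sum()) if self.l1 > 0 else 0.0


class Sequential:
    """A feed-forward stack of layers ending in one logit."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self) -> List[Param]:
        out: List[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(x, train=False))[:, 0]

    # -- weight snapshots (includes batchnorm running stats) --------------
    def get_weights(self) -> List[np.ndarray]:
        out = [p.value.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                out.append(layer.running_mean.copy())
                out.append(layer.running_var.copy())
        return out

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        ps = self.params()
        for p, w in zip(ps, weights[:len(ps)]):
            if p.value.shape != w.shape:
                raise ValueError(f"weight shape {w.shape} != {p.value.shape}")
            p.value = w.astype(np.float32).copy()
        rest = list(weights[len(ps):])
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = rest.pop(0).astype(np.float32).copy()
                layer.running_var = rest.pop(0).astype(np.float32).copy()

    def l1_penalty(self) -> float:
        return sum(layer.l1_penalty() for layer in self.layers
                   if isinstance(layer, Dense))


def bce_loss_and_grad(logits: np.ndarray, labels: np.ndarray):
    """Mean binary cross-entropy from logits; returns (loss, dlogits)."""
    z = logits[:, 0]
    y = labels.astype(np.float64)
    # log(1+exp(-|z|)) formulation for stability
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    p = sigmoid(z)
    dz = ((p - y) / z.shape[0]).astype(np.float32)
    return float(loss), dz[:, None]


class Adam:
    """Adam with optional decoupled weight decay (AdamW when decay > 0)."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad * p.grad
            update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            if self.weight_decay > 0.0:
                update = update + self.weight_decay * p.value
            p.value -= self.lr * update
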