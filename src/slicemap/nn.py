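"""Minimal NumPy neural-network engine (channels-last layout).

Implements exactly the layer set needed by the classifier architectures:
N-dimensional "same" convolution, 2x max pooling, batch/layer
normalization, ReLU, dropout, fully connected layers, a decoupled
weight-decay Adam optimizer (AdamW), step learning-rate decay, and a
numerically stable binary cross-entropy on logits.

All tensors are ``float32`` with shape ``(batch, *spatial, channels)``.
Backward passes are hand-derived; gradients are checked against finite
differences in the test suite.
"""

from __future__ import annotations

import itertools
from typing import Iterable

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv",
    "MaxPool",
    "BatchNorm",
    "LayerNorm",
    "ReLU",
    "Dropout",
    "Flatten",
    "Linear",
    "Sequential",
    "AdamW",
    "StepLR",
    "bce_with_logits",
    "sigmoid",
]


class Param:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # state beyond Params (e.g. batch-norm running moments)
    def extra_state(self) -> dict:
        return {}

    def load_extra_state(self, state: dict) -> None:
        pass


class Conv(Layer):
    """k^ndim convolution with "same" zero padding, stride 1.

    Weight shape is ``(*kernel_offsets, in_ch, out_ch)``; the forward pass
    is a sum over kernel offsets of shifted (N, in_ch) @ (in_ch, out_ch)
    matrix products, which keeps everything inside BLAS.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, ndim: int = 2,
                 rng: np.random.Generator | None = None):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        rng = rng if rng is not None else np.random.default_rng()
        fan_in = in_ch * kernel ** ndim
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(kernel,) * ndim + (in_ch, out_ch))
        self.W = Param(w)
        self.b = Param(np.zeros(out_ch))
        self.kernel = kernel
        self.ndim = ndim
        self.in_ch = in_ch
        self.out_ch = out_ch
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _offsets(self) -> Iterable[tuple[int, ...]]:
        return itertools.product(range(self.kernel), repeat=self.ndim)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != self.ndim + 2:
            raise ValueError(f"expected {self.ndim + 2}-d input, got {x.ndim}-d")
        p = self.kernel // 2
        pad = [(0, 0)] + [(p, p)] * self.ndim + [(0, 0)]
        xp = np.pad(x, pad)
        spatial = x.shape[1:-1]
        n = x.shape[0] * int(np.prod(spatial))
        out = np.zeros((n, self.out_ch), dtype=np.float32)
        cols = [] if training else None
        for off in self._offsets():
            sl = (slice(None),) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial)) + (slice(None),)
            col = np.ascontiguousarray(xp[sl]).reshape(n, self.in_ch)
            out += col @ self.W.value[off]
            if training:
                cols.append(col)
        out += self.b.value
        if training:
            self._cache = (x.shape, xp.shape, cols)
        return out.reshape(x.shape[:-1] + (self.out_ch,))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, xp_shape, cols = self._cache
        spatial = x_shape[1:-1]
        n = x_shape[0] * int(np.prod(spatial))
        g = np.ascontiguousarray(grad).reshape(n, self.out_ch)
        gxp = np.zeros(xp_shape, dtype=np.float32)
        for col, off in zip(cols, self._offsets()):
            self.W.grad[off] += col.T @ g
            gcol = g @ self.W.value[off].T
            sl = (slice(None),) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial)) + (slice(None),)
            gxp[sl] += gcol.reshape(x_shape[:-1] + (self.in_ch,))
        self.b.grad += g.sum(axis=0)
        p = self.kernel // 2
        crop = (slice(None),) + tuple(slice(p, p + s) for s in spatial) + (slice(None),)
        self._cache = None
        return gxp[crop]


class MaxPool(Layer):
    """Non-overlapping max pooling with a fixed integer factor (default 2).

    Odd trailing rows/columns are cropped (floor semantics). Gradient of a
    tied maximum is split uniformly across the tied positions.
    """

    def __init__(self, ndim: int = 2, factor: int = 2):
        self.ndim = ndim
        self.factor = factor
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        f = self.factor
        spatial = x.shape[1:-1]
        cropped = tuple(s - s % f for s in spatial)
        if any(c == 0 for c in cropped):
            raise ValueError(f"spatial extent {spatial} too small for {f}x pooling")
        sl = (slice(None),) + tuple(slice(0, c) for c in cropped) + (slice(None),)
        xc = x[sl]
        grouped = (x.shape[0],) + tuple(
            itertools.chain.from_iterable((c // f, f) for c in cropped)) + (x.shape[-1],)
        xr = xc.reshape(grouped)
        axes = tuple(2 + 2 * i for i in range(self.ndim))
        out = xr.max(axis=axes)
        if training:
            expanded = out
            for ax in axes:
                expanded = np.expand_dims(expanded, ax)
            mask = (xr == expanded)
            count = mask.sum(axis=axes, keepdims=True)
            self._cache = (x.shape, cropped, grouped, axes, sl, mask, count)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, cropped, grouped, axes, sl, mask, count = self._cache
        g = grad
        for ax in axes:
            g = np.expand_dims(g, ax)
        gxr = mask * (g / count)
        gx = np.zeros(x_shape, dtype=np.float32)
        gx[sl] = gxr.reshape((x_shape[0],) + cropped + (x_shape[-1],))
        self._cache = None
        return gx


class BatchNorm(Layer):
    """Per-channel batch normalization over batch and spatial axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def extra_state(self) -> dict:
        return {"running_mean": self.running_mean.copy(),
                "running_var": self.running_var.copy()}

    def load_extra_state(self, state: dict) -> None:
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean = self.running_mean
            var = self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = ((x - mean) * invstd).astype(np.float32)
        if training:
            n = int(np.prod([x.shape[a] for a in axes]))
            self._cache = (xhat, invstd.astype(np.float32), axes, n)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, invstd, axes, n = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gxhat = grad * self.gamma.value
        gx = (invstd / n) * (
            n * gxhat
            - gxhat.sum(axis=axes, keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=axes, keepdims=True)
        )
        self._cache = None
        return gx.astype(np.float32)


class LayerNorm(Layer):
    """Normalization over the trailing feature axis, per sample."""

    def __init__(self, features: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(features))
        self.beta = Param(np.zeros(features))
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = ((x - mean) * invstd).astype(np.float32)
        if training:
            self._cache = (xhat, invstd.astype(np.float32), x.shape[-1])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, invstd, n = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=tuple(range(grad.ndim - 1)))
        self.beta.grad += grad.sum(axis=tuple(range(grad.ndim - 1)))
        gxhat = grad * self.gamma.value
        gx = (invstd / n) * (
            n * gxhat
            - gxhat.sum(axis=-1, keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=-1, keepdims=True)
        )
        self._cache = None
        return gx.astype(np.float32)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gx = grad * self._mask
        self._mask = None
        return gx


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng if rng is not None else np.random.default_rng()
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        self._mask = mask
        return x * mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        gx = grad * self._mask
        self._mask = None
        return gx


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng()
        bound = np.sqrt(1.0 / in_features)
        self.W = Param(rng.uniform(-bound, bound, size=(in_features, out_features)))
        self.b = Param(rng.uniform(-bound, bound, size=out_features))
        self._x = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        gx = grad @ self.W.value.T
        self._x = None
        return gx


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[Param]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_dict(self) -> dict:
        return {
            "params": [p.value.copy() for p in self.params()],
            "extra": [layer.extra_state() for layer in self.layers],
        }

    def load_state_dict(self, state: dict) -> None:
        params = self.params()
        if len(params) != len(state["params"]):
            raise ValueError("state does not match architecture")
        for p, v in zip(params, state["params"]):
            p.value = v.copy()
        for layer, extra in zip(self.layers, state["extra"]):
            layer.load_extra_state(extra)


class AdamW:
    """Adam with decoupled weight decay (applied to every parameter)."""

    def __init__(self, params: list[Param], lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if self.weight_decay:
                p.value -= self.lr * self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * np.square(p.grad)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class StepLR:
    """lr(epoch) = base_lr * gamma ** (epoch // step); epoch is 0-based."""

    def __init__(self, base_lr: float, step: int | None, gamma: float = 0.5):
        self.base_lr = base_lr
        self.step = step
        self.gamma = gamma

    def lr_at(self, epoch: int) -> float:
        if self.step is None:
            return self.base_lr
        return self.base_lr * self.gamma ** (epoch // self.step)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits and its gradient w.r.t. logits."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    loss = float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - y) / z.size).astype(np.float32)
    return loss, grad
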