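"""Minimal numpy neural-network layers with explicit backprop.

Conventions: activations are (batch, length, channels) float32 arrays for
convolutional layers and (batch, features) for dense layers.  Convolutions are
stride-1 "valid"; the transposed convolution exactly inverts the length
arithmetic (L -> L + k - 1) so a mirrored decoder reproduces the input length.
Weights use He-style uniform fan-in initialisation from an explicit generator.
Each parameter carries a group tag so the optimizer can assign per-group
learning rates (pretrained local branch vs the rest).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "group", "name")

    def __init__(self, value: np.ndarray, group: str, name: str):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)
        self.group = group
        self.name = name


def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    params: list

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, group: str, name: str):
        self.w = Param(_he_uniform(rng, (n_in, n_out), n_in), group, f"{name}.w")
        self.b = Param(np.zeros(n_out), group, f"{name}.b")
        self.params = [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gy):
        self.w.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.w.value.T


class Conv1D(Layer):
    """Valid stride-1 1-D convolution; weight shape (k, c_in, c_out)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng, group: str, name: str):
        self.k = k
        self.w = Param(_he_uniform(rng, (k, c_in, c_out), k * c_in), group, f"{name}.w")
        self.b = Param(np.zeros(c_out), group, f"{name}.b")
        self.params = [self.w, self.b]

    def forward(self, x):
        b, l, c = x.shape
        k = self.k
        cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (b, lout, c, k)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(b, l - k + 1, k * c)
        self._cols, self._in_shape = cols, x.shape
        wf = self.w.value.reshape(k * c, -1)
        return cols @ wf + self.b.value

    def backward(self, gy):
        b, lout, cout = gy.shape
        k = self.k
        _, l, c = self._in_shape
        cols2 = self._cols.reshape(b * lout, k * c)
        gy2 = gy.reshape(b * lout, cout)
        self.w.grad += (cols2.T @ gy2).reshape(k, c, cout)
        self.b.grad += gy2.sum(axis=0)
        gx = np.zeros(self._in_shape, dtype=gy.dtype)
        for j in range(k):
            gx[:, j : j + lout, :] += gy @ self.w.value[j].T
        return gx


class ConvTranspose1D(Layer):
    """Transposed conv: maps length L to L + k - 1 (inverse of valid conv)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng, group: str, name: str):
        self.k = k
        self.w = Param(_he_uniform(rng, (k, c_in, c_out), k * c_in), group, f"{name}.w")
        self.b = Param(np.zeros(c_out), group, f"{name}.b")
        self.params = [self.w, self.b]

    def forward(self, x):
        b, l, c = x.shape
        k = self.k
        self._x = x
        y = np.zeros((b, l + k - 1, self.w.value.shape[2]), dtype=x.dtype)
        for j in range(k):
            y[:, j : j + l, :] += x @ self.w.value[j]
        return y + self.b.value

    def backward(self, gy):
        x = self._x
        b, l, c = x.shape
        k = self.k
        self.b.grad += gy.sum(axis=(0, 1))
        gx = np.zeros_like(x)
        x2 = x.reshape(b * l, c)
        for j in range(k):
            seg = gy[:, j : j + l, :]
            self.w.grad[j] += x2.T @ seg.reshape(b * l, -1)
            gx += seg @ self.w.value[j].T
        return gx


class ReLU(Layer):
    params: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pool along the length axis (trailing remainder dropped)."""

    params: list = []

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x):
        b, l, c = x.shape
        lo = l // self.size
        xr = x[:, : lo * self.size, :].reshape(b, lo, self.size, c)
        self._arg = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, gy):
        b, lo, c = gy.shape
        gx = np.zeros(self._in_shape, dtype=gy.dtype)
        gxr = gx[:, : lo * self.size, :].reshape(b, lo, self.size, c)
        bi, li, ci = np.ogrid[:b, :lo, :c]
        gxr[bi, li, self._arg, ci] = gy
        return gx


class Upsample1D(Layer):
    """Nearest-neighbour repetition along the length axis."""

    params: list = []

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x):
        return np.repeat(x, self.factor, axis=1)

    def backward(self, gy):
        b, l, c = gy.shape
        return gy.reshape(b, l // self.factor, self.factor, c).sum(axis=2)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = layers
        self.params = [p for lay in layers for p in lay.params]

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, gy):
        for lay in reversed(self.layers):
            gy = lay.backward(gy)
        return gy


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_backward(p: np.ndarray, gp: np.ndarray) -> np.ndarray:
    """Jacobian-vector product d(loss)/d(logits) given d(loss)/d(p)."""
    inner = (gp * p).sum(axis=-1, keepdims=True)
    return p * (gp - inner)


def sigmoid(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-u))


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = np.sqrt(sum(float((p.grad**2).sum()) for p in params))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale
    return total


class SGD:
    """Minibatch SGD with momentum, per-group learning rates, and global
    gradient-norm clipping (saturating losses like the focal/confidence
    objective produce 1/p-scale spikes that otherwise derail the first steps).
    """

    def __init__(self, params, lr: dict | float, momentum: float = 0.9, max_grad_norm: float = 5.0):
        self.params = list(params)
        self.lr = lr if isinstance(lr, dict) else {"default": lr}
        self.momentum = momentum
        self.max_grad_norm = max_grad_norm
        self.velocity = [np.zeros_like(p.value) for p in self.params]

    def group_lr(self, group: str) -> float:
        return self.lr.get(group, self.lr.get("default", 0.01))

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        clip_grad_norm(self.params, self.max_grad_norm)
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.group_lr(p.group) * p.grad
            p.value += v


class Adam:
    """Adam with per-group learning rates (optional alternative optimizer)."""

    def __init__(self, params, lr: dict | float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr if isinstance(lr, dict) else {"default": lr}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def group_lr(self, group: str) -> float:
        return self.lr.get(group, self.lr.get("default", 0.001))

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mh = self.m[i] / (1 - b1**self.t)
            vh = self.v[i] / (1 - b2**self.t)
            p.value -= self.group_lr(p.group) * mh / (np.sqrt(vh) + self.eps)
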