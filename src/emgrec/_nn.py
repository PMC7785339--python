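"""Minimal numpy neural-network layers for the lightweight CNN.

Implements exactly what the classifier needs — 3x3 'same' convolution via
im2col, batch normalization, 2x2 'same' max pooling, dense layers, dropout,
softmax cross-entropy and Adam — with deterministic, seeded initialization
and updates. Arrays are NHWC: (batch, height, width, channels).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "BatchNorm", "ReLU", "MaxPool2x2", "Flatten", "Dense",
           "Dropout", "Sequential", "Adam", "softmax", "cross_entropy_grad"]


def _pad_same(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    ph, pw = kh // 2, kw // 2
    return np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, kh*kw*C) patches for stride-1 'same' conv."""
    n, h, w, c = x.shape
    xp = _pad_same(x, kh, kw)
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(n, h, w, kh, kw, c),
        strides=(s[0], s[1], s[2], s[1], s[2], s[3]), writeable=False)
    return view.reshape(n * h * w, kh * kw * c)


def _col2im(cols: np.ndarray, shape, kh: int, kw: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the input."""
    n, h, w, c = shape
    ph, pw = kh // 2, kw // 2
    out = np.zeros((n, h + 2 * ph, w + 2 * pw, c))
    cols = cols.reshape(n, h, w, kh, kw, c)
    for i in range(kh):
        for j in range(kw):
            out[:, i:i + h, j:j + w, :] += cols[:, :, :, i, j, :]
    return out[:, ph:ph + h, pw:pw + w, :]


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x, train: bool, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2D(Layer):
    """Stride-1 'same' 2-D convolution with bias (He-initialized)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kh = self.kw = kernel
        fan_in = kernel * kernel * c_in
        self.params = {
            "W": rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in),
            "b": np.zeros(c_out),
        }

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        self._cols = _im2col(x, self.kh, self.kw)
        n, h, w, _ = x.shape
        out = self._cols @ self.params["W"] + self.params["b"]
        return out.reshape(n, h, w, -1)

    def backward(self, grad):
        n, h, w, c_out = grad.shape
        g = grad.reshape(n * h * w, c_out)
        self.grads = {"W": self._cols.T @ g, "b": g.sum(axis=0)}
        dcols = g @ self.params["W"].T
        return _col2im(dcols, self._shape, self.kh, self.kw)


class BatchNorm(Layer):
    """Per-channel batch normalization over all other axes.

    Training uses batch statistics and tracks running moments (momentum 0.9);
    inference uses the running statistics.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._m = x.size // x.shape[-1]
        self._train = train
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad):
        axes = self._axes
        self.grads = {"gamma": np.sum(grad * self._xhat, axis=axes),
                      "beta": np.sum(grad, axis=axes)}
        g = grad * self.params["gamma"]
        if not self._train:
            return g / self._std
        m = self._m
        return (g - g.mean(axis=axes)
                - self._xhat * np.mean(g * self._xhat, axis=axes)) / self._std \
            if m > 1 else g / self._std


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2x2(Layer):
    """2x2, stride-2 max pooling with 'same' (ceil) padding."""

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        ho, wo = -(-h // 2), -(-w // 2)
        xp = np.full((n, ho * 2, wo * 2, c), -np.inf)
        xp[:, :h, :w, :] = x
        blocks = xp.reshape(n, ho, 2, wo, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = blocks.reshape(n, ho, wo, c, 4)
        self._arg = flat.argmax(axis=-1)
        self._in_shape = (n, h, w, c)
        return flat.max(axis=-1)

    def backward(self, grad):
        n, h, w, c = self._in_shape
        ho, wo = grad.shape[1], grad.shape[2]
        flat = np.zeros((n, ho, wo, c, 4))
        np.put_along_axis(flat, self._arg[..., None], grad[..., None], axis=-1)
        xp = flat.reshape(n, ho, wo, c, 2, 2).transpose(0, 1, 4, 2, 5, 3) \
                 .reshape(n, ho * 2, wo * 2, c)
        return xp[:, :h, :w, :]


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in),
            "b": np.zeros(d_out),
        }

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads = {"W": self._x.T @ grad, "b": grad.sum(axis=0)}
        return grad @ self.params["W"].T


class Dropout(Layer):
    def __init__(self, p: float):
        super().__init__()
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield (li, name), p


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p) for k, p in model.parameters()}
        self.v = {k: np.zeros_like(p) for k, p in model.parameters()}

    def step(self):
        self.t += 1
        for li, layer in enumerate(self.model.layers):
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                k = (li, name)
                self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
                self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
                mhat = self.m[k] / (1 - self.b1 ** self.t)
                vhat = self.v[k] / (1 - self.b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n
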