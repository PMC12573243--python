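"""Minimal NumPy neural-network layer used by the autoencoder stages.

Implements exactly the pieces the pipeline needs — dense and 3x3
same-padded convolutional layers, batch normalization, 2x2 max pooling,
nearest-neighbour upsampling, ReLU, Glorot-uniform initialization, MSE
loss and the Adam optimizer — with explicit forward/backward passes so
training is fully deterministic given a seed and runs on one CPU without
any deep-learning framework.

All arrays are float32 (a deliberate speed choice for one CPU).  Inference-mode passes (``training=False``) use
batch-norm running statistics, so the output for one sample never
depends on the rest of the batch.
"""

from __future__ import annotations

import numpy as np

from .errors import TrainingError

DTYPE = np.float32

__all__ = [
    "DTYPE",
    "glorot_uniform",
    "Parameter",
    "Layer",
    "Dense",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Upsample2d",
    "Flatten",
    "Reshape",
    "Sequential",
    "Adam",
    "mse_loss",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    """Draw from U(-limit, limit) with limit = sqrt(6 / (fan_in + fan_out))."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []

    def state(self) -> dict[str, np.ndarray]:
        """All arrays (parameters and buffers) needed to restore the layer."""
        return {}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for key, arr in self.state().items():
            arr[...] = state[key]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = Parameter(glorot_uniform(rng, (n_in, n_out), n_in, n_out))
        self.b = Parameter(np.zeros(n_out, dtype=DTYPE)) if bias else None
        self._x = None

    def forward(self, x, training):
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        if self.b is not None:
            self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def state(self):
        s = {"W": self.W.value}
        if self.b is not None:
            s["b"] = self.b.value
        return s


class Conv2d(Layer):
    """3x3 (or kxk) convolution, stride 1, zero same-padding, NCHW layout."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        fan_out = c_out * k * k
        self.W = Parameter(glorot_uniform(rng, (c_out, c_in * k * k), fan_in, fan_out))
        self.b = Parameter(np.zeros(c_out, dtype=DTYPE))
        self._cols = None
        self._shape = None

    def _im2col(self, xp, H, W):
        N, C = xp.shape[:2]
        k = self.k
        cols = np.empty((N, C, k, k, H, W), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i : i + H, j : j + W]
        return cols.reshape(N, C * k * k, H * W)

    def forward(self, x, training):
        N, C, H, W = x.shape
        p = self.k // 2
        xp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=DTYPE)
        xp[:, :, p : p + H, p : p + W] = x
        cols = self._im2col(xp, H, W)
        self._cols = cols
        self._shape = (N, C, H, W)
        y = np.matmul(self.W.value, cols)  # (N, c_out, H*W)
        y += self.b.value[:, None]
        return y.reshape(N, self.c_out, H, W)

    def backward(self, dy):
        N, C, H, W = self._shape
        k, p = self.k, self.k // 2
        dyf = dy.reshape(N, self.c_out, H * W)
        self.W.grad += np.matmul(dyf, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.b.grad += dyf.sum(axis=(0, 2))
        if getattr(self, "skip_input_grad", False):
            return None
        dcols = np.matmul(self.W.value.T, dyf).reshape(N, C, k, k, H, W)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + H, j : j + W] += dcols[:, :, i, j]
        return dxp[:, :, p : p + H, p : p + W]

    def parameters(self):
        return [self.W, self.b]

    def state(self):
        return {"W": self.W.value, "b": self.b.value}


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W); running stats at inference."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c, dtype=DTYPE))
        self.beta = Parameter(np.zeros(c, dtype=DTYPE))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self._cache = None

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, dy):
        xhat, inv_std = self._cache
        M = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[:, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv_std[:, None, None] / M) * (M * dxhat - s1 - xhat * s2)

    def parameters(self):
        return [self.gamma, self.beta]

    def state(self):
        return {
            "gamma": self.gamma.value,
            "beta": self.beta.value,
            "running_mean": self.running_mean,
            "running_var": self.running_var,
        }


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2."""

    def forward(self, x, training):
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = (N, C, H, W)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        N, C, H, W = self._shape
        dxr = np.zeros((N, C, H // 2, W // 2, 4), dtype=DTYPE)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        return dxr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)


class Upsample2d(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x, training):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        N, C, H2, W2 = dy.shape
        return dy.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, *shape: int):
        self.shape = shape

    def forward(self, x, training):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], *self.shape)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def state(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for key, arr in layer.state().items():
                out[f"{i}.{key}"] = arr
        return out


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements; returns (loss, dL/dpred)."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    if not np.isfinite(loss):
        raise TrainingError(f"non-finite MSE loss: {loss}")
    return loss, (2.0 / diff.size) * diff
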