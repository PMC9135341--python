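"""Minimal NumPy layer engine for 1-D sequence convolutional networks.

Layers implement ``forward``/``backward`` with explicit caching, and expose
their trainable arrays through :meth:`Layer.parameters`.  ``backward`` always
returns the gradient with respect to the layer input, so gradients propagate
all the way to the one-hot sequence — the property the saliency machinery
relies on.

Conventions: activations have shape ``(batch, length, channels)``;
convolutions use 'same' padding (output length ``ceil(L / stride)``), the
padding split left/right with the extra base on the right.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Layer",
    "Conv1d",
    "Dense",
    "ReLU",
    "Sigmoid",
    "MaxPool1d",
    "Flatten",
    "Dropout",
    "Sequential",
    "ResidualBlock",
]


class Layer:
    """Base class: a differentiable operation with optional parameters."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[np.ndarray]:
        """Trainable arrays, in a stable order."""
        return []

    def gradients(self) -> list[np.ndarray]:
        """Gradient arrays aligned with :meth:`parameters`."""
        return []


def _he_normal(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Layer):
    """1-D convolution with 'same' padding, arbitrary stride, im2col matmul."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        if kernel < 1 or stride < 1 or c_in < 1 or c_out < 1:
            raise ValueError("Conv1d dimensions must be positive")
        rng = rng if rng is not None else np.random.default_rng()
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.w = _he_normal(rng, kernel * c_in, (kernel * c_in, c_out))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def _pad(self, length: int) -> tuple[int, int, int]:
        l_out = -(-length // self.stride)  # ceil
        total = max((l_out - 1) * self.stride + self.kernel - length, 0)
        return l_out, total // 2, total - total // 2

    def out_length(self, length: int) -> int:
        return self._pad(length)[0]

    def forward(self, x, train=False):
        batch, length, _ = x.shape
        l_out, pl, pr = self._pad(length)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        win = win[:, :: self.stride]                       # (B, L_out, C, k)
        cols = win.transpose(0, 1, 3, 2).reshape(batch, l_out, self.kernel * self.c_in)
        self._cache = (cols, length, pl, xp.shape[1])
        return cols @ self.w + self.b

    def backward(self, dy):
        cols, length, pl, lp = self._cache
        batch, l_out, _ = dy.shape
        kc = self.kernel * self.c_in
        self.dw = cols.reshape(-1, kc).T @ dy.reshape(-1, self.c_out)
        self.db = dy.sum(axis=(0, 1))
        dcols = (dy @ self.w.T).reshape(batch, l_out, self.kernel, self.c_in)
        dxp = np.zeros((batch, lp, self.c_in))
        for j in range(self.kernel):
            dxp[:, j : j + self.stride * l_out : self.stride] += dcols[:, :, j]
        return dxp[:, pl : pl + length]

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.dw, self.db]


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng()
        self.w = _he_normal(rng, d_in, (d_in, d_out))
        self.b = np.zeros(d_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.dw, self.db]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing partial window is dropped."""

    def __init__(self, kernel: int):
        if kernel < 1:
            raise ValueError("pool kernel must be positive")
        self.kernel = kernel

    def out_length(self, length: int) -> int:
        return length // self.kernel

    def forward(self, x, train=False):
        batch, length, ch = x.shape
        l_out = length // self.kernel
        xt = x[:, : l_out * self.kernel].reshape(batch, l_out, self.kernel, ch)
        self._idx = xt.argmax(axis=2)
        self._shape = (batch, length, ch, l_out)
        return np.take_along_axis(xt, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        batch, length, ch, l_out = self._shape
        dxt = np.zeros((batch, l_out, self.kernel, ch))
        np.put_along_axis(dxt, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((batch, length, ch))
        dx[:, : l_out * self.kernel] = dxt.reshape(batch, l_out * self.kernel, ch)
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng if rng is not None else np.random.default_rng()

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self):
        return [g for layer in self.layers for g in layer.gradients()]


class ResidualBlock(Layer):
    """conv → ReLU → conv, added to a shortcut, then a final ReLU.

    When the channel count changes the shortcut is a width-1 strided
    convolution and the first conv uses the same stride (downsampling);
    otherwise the shortcut is the identity and both convs have stride 1.
    With all conv weights and biases zero, an identity-shortcut block
    computes ReLU(x).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator | None = None):
        stride = 1 if c_in == c_out else 2
        self.conv1 = Conv1d(c_in, c_out, kernel, stride=stride, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(c_out, c_out, kernel, stride=1, rng=rng)
        self.shortcut = None if c_in == c_out else Conv1d(c_in, c_out, 1, stride=stride, rng=rng)
        self.relu_out = ReLU()

    def out_length(self, length: int) -> int:
        return self.conv1.out_length(length)

    def forward(self, x, train=False):
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x, train), train), train)
        sc = x if self.shortcut is None else self.shortcut.forward(x, train)
        return self.relu_out.forward(h + sc, train)

    def backward(self, dy):
        dz = self.relu_out.backward(dy)
        dx = self.conv1.backward(self.relu1.backward(self.conv2.backward(dz)))
        dx_sc = dz if self.shortcut is None else self.shortcut.backward(dz)
        return dx + dx_sc

    def parameters(self):
        out = self.conv1.parameters() + self.conv2.parameters()
        if self.shortcut is not None:
            out += self.shortcut.parameters()
        return out

    def gradients(self):
        out = self.conv1.gradients() + self.conv2.gradients()
        if self.shortcut is not None:
            out += self.shortcut.gradients()
        return out
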