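"""3-D convolutional layers with analytic backward passes.

Activations are single-sample tensors of shape (channels, D, H, W) in
float32.  Convolutions are evaluated as a sum of per-offset matrix
products (one BLAS call per kernel tap), which is both fast in numpy and
trivially differentiable.  Each layer instance is used once per forward
pass and caches exactly what its backward pass needs.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv3d(Layer):
    """3-D convolution, stride 1, 'same' padding for odd kernels."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator,
                 name: str = "conv") -> None:
        if ksize not in (1, 3):
            raise ValueError("only 1x1x1 and 3x3x3 kernels are used in this network")
        fan_in = c_in * ksize ** 3
        std = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.w = Param(rng.standard_normal((c_out, c_in, ksize, ksize, ksize)) * std,
                       f"{name}.w")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self.ksize = ksize
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c_out, c_in, k = self.w.data.shape[0], self.w.data.shape[1], self.ksize
        d, h, w_ = x.shape[1:]
        if k == 1:
            xf = x.reshape(c_in, -1)
            self._cache = (x.shape, xf)
            out = self.w.data.reshape(c_out, c_in) @ xf + self.b.data[:, None]
            return out.reshape(c_out, d, h, w_)
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
        self._cache = (x.shape, xp)
        out = np.zeros((c_out, d * h * w_), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = np.ascontiguousarray(xp[:, i:i + d, j:j + h, l:l + w_])
                    out += self.w.data[:, :, i, j, l] @ xs.reshape(c_in, -1)
        out += self.b.data[:, None]
        return out.reshape(c_out, d, h, w_)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c_out, c_in, k = self.w.data.shape[0], self.w.data.shape[1], self.ksize
        d, h, w_ = dy.shape[1:]
        dyf = dy.reshape(c_out, -1)
        self.b.grad += dyf.sum(axis=1)
        if k == 1:
            shape, xf = self._cache
            self.w.grad += (dyf @ xf.T).reshape(self.w.data.shape)
            dx = self.w.data.reshape(c_out, c_in).T @ dyf
            return dx.reshape(shape)
        shape, xp = self._cache
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = np.ascontiguousarray(xp[:, i:i + d, j:j + h, l:l + w_])
                    self.w.grad[:, :, i, j, l] += dyf @ xs.reshape(c_in, -1).T
                    dxp[:, i:i + d, j:j + h, l:l + w_] += (
                        self.w.data[:, :, i, j, l].T @ dyf
                    ).reshape(c_in, d, h, w_)
        pad = k // 2
        return np.ascontiguousarray(dxp[:, pad:-pad, pad:-pad, pad:-pad])


class MaxPool3d(Layer):
    """2×2×2 max pooling; ties propagate the gradient to every maximizer."""

    def __init__(self) -> None:
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"maxpool requires even dims, got {(d, h, w)}")
        xr = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(2, 4, 6))
        self._cache = (xr, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xr, y = self._cache
        mask = xr == y[:, :, None, :, None, :, None]
        dx = mask * dy[:, :, None, :, None, :, None]
        c, d2, _, h2, _, w2, _ = xr.shape
        return np.ascontiguousarray(dx.reshape(c, d2 * 2, h2 * 2, w2 * 2))


class ConvTranspose3d(Layer):
    """2×2×2 transposed convolution with stride 2 (convolutional upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 name: str = "up") -> None:
        std = np.sqrt(2.0 / c_in)
        self.w = Param(rng.standard_normal((c_out, c_in, 2, 2, 2)) * std, f"{name}.w")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c_in, d, h, w = x.shape
        c_out = self.w.data.shape[0]
        xf = x.reshape(c_in, -1)
        self._cache = (x.shape, xf)
        out = np.empty((c_out, 2 * d, 2 * h, 2 * w), dtype=DTYPE)
        for i in range(2):
            for j in range(2):
                for l in range(2):
                    out[:, i::2, j::2, l::2] = (
                        self.w.data[:, :, i, j, l] @ xf
                    ).reshape(c_out, d, h, w)
        out += self.b.data[:, None, None, None]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        shape, xf = self._cache
        c_in, d, h, w = shape
        c_out = self.w.data.shape[0]
        self.b.grad += dy.sum(axis=(1, 2, 3))
        dx = np.zeros((c_in, d * h * w), dtype=DTYPE)
        for i in range(2):
            for j in range(2):
                for l in range(2):
                    dslice = np.ascontiguousarray(dy[:, i::2, j::2, l::2]).reshape(c_out, -1)
                    self.w.grad[:, :, i, j, l] += dslice @ xf.T
                    dx += self.w.data[:, :, i, j, l].T @ dslice
        return dx.reshape(shape)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(DTYPE, copy=False)


class Softplus(Layer):
    """Numerically stable softplus; enforces strictly positive outputs."""

    def __init__(self) -> None:
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.logaddexp(0.0, x).astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        sig = 0.5 * (1.0 + np.tanh(0.5 * self._x))  # overflow-safe sigmoid
        return (dy * sig).astype(DTYPE, copy=False)


class ResBlock(Layer):
    """conv3-ReLU-conv3 with an identity (or 1×1×1-projected) shortcut."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 name: str = "res") -> None:
        self.conv1 = Conv3d(c_in, c_out, 3, rng, f"{name}.conv1")
        self.relu1 = ReLU()
        self.conv2 = Conv3d(c_out, c_out, 3, rng, f"{name}.conv2")
        self.proj = Conv3d(c_in, c_out, 1, rng, f"{name}.proj") if c_in != c_out else None
        self.relu2 = ReLU()

    def params(self) -> list[Param]:
        out = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        shortcut = self.proj.forward(x) if self.proj is not None else x
        return self.relu2.forward(y + shortcut)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dy)
        dx_main = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        dx_short = self.proj.backward(d) if self.proj is not None else d
        return dx_main + dx_short
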