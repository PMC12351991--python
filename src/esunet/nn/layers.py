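"""Layers with explicit forward/backward passes on (C, D, H, W) tensors.

Convolutions use im2col + BLAS matmul; to keep memory bounded the column
matrix is rebuilt during backward instead of cached.  Every layer stores
only what its backward needs and each layer instance is used once per
forward pass.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_DTYPE = np.float32


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=_DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base layer: parameter discovery by attribute walk, train/eval mode."""

    training: bool = True

    def params(self) -> list[Param]:
        found: list[Param] = []
        for attr in vars(self).values():
            if isinstance(attr, Param):
                found.append(attr)
            elif isinstance(attr, Module):
                found.extend(attr.params())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Param):
                        found.append(item)
                    elif isinstance(item, Module):
                        found.extend(item.params())
        return found

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for attr in vars(self).values():
            if isinstance(attr, Module):
                attr.set_training(mode)
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        item.set_training(mode)

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        found: list[np.ndarray] = []
        for attr in vars(self).values():
            if isinstance(attr, Module):
                found.extend(attr.buffers())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        found.extend(item.buffers())
        return found

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    __call__ = lambda self, x: self.forward(x)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, D, H, W) -> (C*k^3, D*H*W) column matrix with 'same' zero padding.

    Assembled offset-by-offset with strided slice copies (no large-axis
    transposes), matching the (C_out, C_in*k^3) weight-matrix layout.
    """
    c, d, h, w = x.shape
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    v = d * h * w
    cols = np.empty((c, k**3, v), dtype=_DTYPE)
    idx = 0
    for a in range(k):
        for b in range(k):
            for cc in range(k):
                cols[:, idx, :] = xp[:, a:a + d, b:b + h, cc:cc + w].reshape(c, v)
                idx += 1
    return cols.reshape(c * k**3, v)


class Conv3d(Module):
    """3D convolution, stride 1, 'same' zero padding, kernel 1 or 3."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True) -> None:
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel**3
        self.weight = Param(_he_init(rng, (c_out, c_in, kernel, kernel, kernel), fan_in), "conv.w")
        self.bias = Param(np.zeros(c_out), "conv.b") if bias else None
        self._x: np.ndarray | None = None
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        self._x = x
        c, d, h, w = x.shape
        wmat = self.weight.value.reshape(self.c_out, -1)
        if self.kernel == 1:
            y = (wmat @ x.reshape(c, -1)).reshape(self.c_out, d, h, w)
        else:
            cols = _im2col(x, 3)
            self._cols = cols if self.training else None
            y = (wmat @ cols).reshape(self.c_out, d, h, w)
        if self.bias is not None:
            y += self.bias.value[:, None, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        c, d, h, w = x.shape
        v = d * h * w
        dy_flat = np.ascontiguousarray(dy, dtype=_DTYPE).reshape(self.c_out, v)
        wmat = self.weight.value.reshape(self.c_out, -1)
        if self.bias is not None:
            self.bias.grad += dy_flat.sum(axis=1)
        if self.kernel == 1:
            self.weight.grad += (dy_flat @ x.reshape(c, v).T).reshape(self.weight.value.shape)
            return (wmat.T @ dy_flat).reshape(c, d, h, w)
        cols = self._cols if self._cols is not None else _im2col(x, 3)
        self._cols = None
        self.weight.grad += (dy_flat @ cols.T).reshape(self.weight.value.shape)
        dcols = (wmat.T @ dy_flat).reshape(c, 27, d, h, w)
        dxp = np.zeros((c, d + 2, h + 2, w + 2), dtype=_DTYPE)
        idx = 0
        for a in range(3):
            for b in range(3):
                for cc in range(3):
                    dxp[:, a:a + d, b:b + h, cc:cc + w] += dcols[:, idx]
                    idx += 1
        return dxp[:, 1:1 + d, 1:1 + h, 1:1 + w]


class ConvTranspose3d(Module):
    """Transposed convolution, kernel 2, stride 2 (non-overlapping)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        self.c_in, self.c_out = c_in, c_out
        self.weight = Param(_he_init(rng, (c_in, c_out, 2, 2, 2), c_in * 8), "tconv.w")
        self.bias = Param(np.zeros(c_out), "tconv.b")
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        self._x = x
        c, d, h, w = x.shape
        t = np.tensordot(x, self.weight.value, axes=([0], [0]))  # (D,H,W,Co,2,2,2)
        y = t.transpose(3, 0, 4, 1, 5, 2, 6).reshape(self.c_out, 2 * d, 2 * h, 2 * w)
        return y + self.bias.value[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        c, d, h, w = x.shape
        self.bias.grad += dy.sum(axis=(1, 2, 3))
        dt = np.ascontiguousarray(
            dy.reshape(self.c_out, d, 2, h, 2, w, 2).transpose(1, 3, 5, 0, 2, 4, 6),
            dtype=_DTYPE,
        )  # (D,H,W,Co,2,2,2)
        self.weight.grad += np.tensordot(x, dt, axes=([1, 2, 3], [0, 1, 2]))
        dx = np.tensordot(dt, self.weight.value, axes=([3, 4, 5, 6], [1, 2, 3, 4]))
        return np.ascontiguousarray(dx.transpose(3, 0, 1, 2))


class BatchNorm3d(Module):
    """Per-channel normalisation over the spatial extent of one sample.

    With batch size 1, batch statistics reduce to spatial statistics per
    channel; running estimates are kept for evaluation mode.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        self.gamma = Param(np.ones(c), "bn.gamma")
        self.beta = Param(np.zeros(c), "bn.beta")
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(c, dtype=_DTYPE)
        self.running_var = np.ones(c, dtype=_DTYPE)
        self._cache = None

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        if self.training:
            mu = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None, None]) * inv[:, None, None, None]
        self._cache = (xhat, inv)
        return self.gamma.value[:, None, None, None] * xhat + self.beta.value[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n = float(np.prod(dy.shape[1:]))
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += dy.sum(axis=(1, 2, 3))
        dxhat = dy * self.gamma.value[:, None, None, None]
        if not self.training:
            return dxhat * inv[:, None, None, None]
        s1 = dxhat.sum(axis=(1, 2, 3))[:, None, None, None]
        s2 = (dxhat * xhat).sum(axis=(1, 2, 3))[:, None, None, None]
        return (inv[:, None, None, None] / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(_DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class MaxPool3d(Module):
    """Max pooling with kernel == stride (2, 4, or 8)."""

    def __init__(self, stride: int) -> None:
        self.s = int(stride)

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.s
        c, d, h, w = x.shape
        if d % s or h % s or w % s:
            raise ValueError(f"spatial dims {x.shape[1:]} not divisible by pool stride {s}")
        blocks = (
            x.reshape(c, d // s, s, h // s, s, w // s, s)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(c, d // s, h // s, w // s, s**3)
        )
        self._arg = blocks.argmax(axis=-1)
        self._shape = x.shape
        return blocks.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s = self.s
        c, d, h, w = self._shape
        blocks = np.zeros((c, d // s, h // s, w // s, s**3), dtype=_DTYPE)
        np.put_along_axis(blocks, self._arg[..., None], dy[..., None].astype(_DTYPE), axis=-1)
        return (
            blocks.reshape(c, d // s, h // s, w // s, s, s, s)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, d, h, w)
        )


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_out, n_in) linear-interpolation matrix, half-pixel centres."""
    m = np.zeros((n_out, n_in), dtype=_DTYPE)
    x = np.clip((np.arange(n_out) + 0.5) * n_in / n_out - 0.5, 0, n_in - 1)
    lo = np.floor(x).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w = x - lo
    m[np.arange(n_out), lo] += 1.0 - w
    m[np.arange(n_out), hi] += w
    return m


def _apply_axis_matrix(arr: np.ndarray, m: np.ndarray, axis: int) -> np.ndarray:
    moved = np.moveaxis(arr, axis, -1)
    return np.moveaxis(moved @ m.T, -1, axis)


class TrilinearUp(Module):
    """Parameter-free trilinear upsampling by an integer factor."""

    def __init__(self, factor: int) -> None:
        self.factor = int(factor)
        self._mats: dict[int, np.ndarray] = {}

    def _mat(self, n_in: int) -> np.ndarray:
        if n_in not in self._mats:
            self._mats[n_in] = _interp_matrix(n_in, n_in * self.factor)
        return self._mats[n_in]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        y = np.asarray(x, dtype=_DTYPE)
        for axis in (1, 2, 3):
            y = _apply_axis_matrix(y, self._mat(x.shape[axis]), axis)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.asarray(dy, dtype=_DTYPE)
        for axis in (1, 2, 3):
            dx = _apply_axis_matrix(dx, self._mat(self._in_shape[axis]).T, axis)
        return np.ascontiguousarray(dx)


class ChannelAttention(Module):
    """Squeeze-and-excitation gate: global average pool -> bottleneck -> sigmoid.

    The bottleneck width is round(ratio * C) with a floor of 1.  The
    bottleneck activation is leaky (slope 0.01) so narrow bottlenecks — a
    single unit at tiny channel counts — cannot start gradient-dead.
    """

    _LEAK = 0.01

    def __init__(self, c: int, ratio: float, rng: np.random.Generator) -> None:
        hidden = max(1, int(round(ratio * c)))
        self.c, self.hidden = c, hidden
        self.w1 = Param(_he_init(rng, (hidden, c), c), "se.w1")
        self.b1 = Param(np.zeros(hidden), "se.b1")
        self.w2 = Param(_he_init(rng, (c, hidden), hidden), "se.w2")
        self.b2 = Param(np.zeros(c), "se.b2")
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        s = x.mean(axis=(1, 2, 3))
        a1 = self.w1.value @ s + self.b1.value
        z = np.where(a1 > 0, a1, self._LEAK * a1)
        a2 = self.w2.value @ z + self.b2.value
        g = 1.0 / (1.0 + np.exp(-a2))
        self._cache = (x, s, a1, z, g)
        return x * g[:, None, None, None].astype(_DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s, a1, z, g = self._cache
        v = float(np.prod(x.shape[1:]))
        dg = (dy * x).sum(axis=(1, 2, 3))
        dx = dy * g[:, None, None, None]
        da2 = dg * g * (1.0 - g)
        self.w2.grad += np.outer(da2, z)
        self.b2.grad += da2
        dz = self.w2.value.T @ da2
        da1 = np.where(a1 > 0, dz, self._LEAK * dz)
        self.w1.grad += np.outer(da1, s)
        self.b1.grad += da1
        ds = self.w1.value.T @ da1
        return dx + (ds / v)[:, None, None, None].astype(_DTYPE)


class Sequential(Module):
    def __init__(self, *modules: Module) -> None:
        self.modules = list(modules)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            dy = m.backward(dy)
        return dy
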