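"""Minimal 3D conv-net layers with explicit forward/backward passes.

Everything operates on float32 arrays shaped (batch, channels, D, H, W).
Each layer caches what its backward pass needs on ``forward`` and releases
it on ``backward``.  Convolutions are evaluated as im2col matrix products;
their input gradient is assembled by scatter-adding over kernel offsets,
which is exact and fast at the kernel sizes used here (<= 7).

Trainable arrays are wrapped in :class:`Param` so the optimizer can walk a
flat parameter list; batch-norm running statistics are buffers, not
parameters, and are excluded from parameter counts.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("name", "value", "grad", "lr_mult", "decay")

    def __init__(self, name: str, value: np.ndarray, lr_mult: float = 1.0, decay: bool = True):
        self.name = name
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.lr_mult = float(lr_mult)
        self.decay = decay  # participates in L2 regularization


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv3d(Layer):
    """3D convolution (cross-correlation), zero padding, no bias.

    Weight layout is (C_out, C_in, k, k, k); bias is omitted because every
    convolution here is followed by batch normalization.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        pad: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
        name: str = "conv",
    ):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3
        fan_out = c_out * kernel**3
        self.weight = Param(
            name, glorot_uniform(rng, (c_out, c_in, kernel, kernel, kernel), fan_in, fan_out)
        )
        self._cache: Optional[tuple] = None

    def params(self) -> list[Param]:
        return [self.weight]

    def _offsets(self):
        k = self.k
        for a in range(k):
            for bb in range(k):
                for cc in range(k):
                    yield a, bb, cc

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        b, c = xp.shape[:2]
        do = (xp.shape[2] - k) // s + 1
        ho = (xp.shape[3] - k) // s + 1
        wo = (xp.shape[4] - k) // s + 1
        bv = b * do * ho * wo
        # offset-major column buffer: one contiguous (BV, C_in) slab per kernel
        # offset, accumulated into the output by k^3 small matrix products
        cols = np.empty((k**3, bv, c), dtype=np.float32)
        for o, (a, bb, cc) in enumerate(self._offsets()):
            patch = xp[:, :, a : a + s * do : s, bb : bb + s * ho : s, cc : cc + s * wo : s]
            cols[o] = patch.transpose(0, 2, 3, 4, 1).reshape(bv, c)
        w2 = self.weight.value.reshape(self.c_out, c, k**3).transpose(2, 1, 0)
        y = np.zeros((bv, self.c_out), dtype=np.float32)
        for o in range(k**3):
            y += cols[o] @ w2[o]
        self._cache = (cols, xp.shape, x.shape, (b, do, ho, wo))
        return np.ascontiguousarray(
            y.reshape(b, do, ho, wo, self.c_out).transpose(0, 4, 1, 2, 3)
        )

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, padded_shape, x_shape, (b, do, ho, wo) = self._cache
        self._cache = None
        k, s, p = self.k, self.stride, self.pad
        c = self.c_in
        bv = b * do * ho * wo
        g = np.ascontiguousarray(gy.transpose(0, 2, 3, 4, 1).reshape(bv, self.c_out))
        w2 = self.weight.value.reshape(self.c_out, c, k**3).transpose(2, 1, 0)
        dw2 = np.empty((k**3, c, self.c_out), dtype=np.float32)
        dxp = np.zeros(padded_shape, dtype=np.float32)
        for o, (a, bb, cc) in enumerate(self._offsets()):
            dw2[o] = cols[o].T @ g
            dcol = (g @ w2[o].T).reshape(b, do, ho, wo, c).transpose(0, 4, 1, 2, 3)
            dxp[:, :, a : a + s * do : s, bb : bb + s * ho : s, cc : cc + s * wo : s] += dcol
        self.weight.grad += dw2.transpose(2, 1, 0).reshape(self.weight.value.shape)
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        return np.ascontiguousarray(dxp[:, :, : x_shape[2], : x_shape[3], : x_shape[4]])


class BatchNorm3d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.c = c
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(f"{name}.gamma", np.ones(c, dtype=np.float32), decay=False)
        self.beta = Param(f"{name}.beta", np.zeros(c, dtype=np.float32), decay=False)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache: Optional[tuple] = None
        self._accum: Optional[list] = None  # [n, sum(x), sum(x^2)] during recalibration

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def begin_accumulate(self) -> None:
        self._accum = [0, np.zeros(self.c, dtype=np.float64), np.zeros(self.c, dtype=np.float64)]

    def end_accumulate(self) -> None:
        n, sx, sx2 = self._accum
        self._accum = None
        if n > 0:
            mean = sx / n
            self.running_mean = mean.astype(np.float32)
            self.running_var = np.maximum(sx2 / n - mean**2, 0.0).astype(np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self._accum is not None:
                n = x.shape[0] * x.shape[2] * x.shape[3] * x.shape[4]
                self._accum[0] += n
                self._accum[1] += x.sum(axis=axes, dtype=np.float64)
                self._accum[2] += (x.astype(np.float64) ** 2).sum(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, self.c, 1, 1, 1)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        y = self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)
        self._cache = (xhat, inv, train, x.shape)
        return y.astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv, train, x_shape = self._cache
        self._cache = None
        shape = (1, self.c, 1, 1, 1)
        axes = (0, 2, 3, 4)
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g = gy * self.gamma.value.reshape(shape)
        if not train:
            return (g * inv.reshape(shape)).astype(np.float32)
        m = x_shape[0] * x_shape[2] * x_shape[3] * x_shape[4]
        dxhat = g
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shape)
        ) * inv.reshape(shape)
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        m = self._mask
        self._mask = None
        return np.where(m, gy, 0.0).astype(np.float32)


class MaxPool3d(Layer):
    """Max pooling, kernel 3 / stride 2 / pad 1 by default (residual-stem style)."""

    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = kernel, stride, pad
        self._cache: Optional[tuple] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)), constant_values=-np.inf)
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        b, c, do, ho, wo = win.shape[:5]
        flat = win.reshape(b, c, do, ho, wo, k**3)
        arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, x.shape, xp.shape, (b, c, do, ho, wo))
        return np.ascontiguousarray(y.astype(np.float32))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        arg, x_shape, xp_shape, (b, c, do, ho, wo) = self._cache
        self._cache = None
        k, s, p = self.k, self.stride, self.pad
        az, ay, ax = np.unravel_index(arg, (k, k, k))
        iz = np.arange(do)[None, None, :, None, None] * s + az
        iy = np.arange(ho)[None, None, None, :, None] * s + ay
        ix = np.arange(wo)[None, None, None, None, :] * s + ax
        ib = np.arange(b)[:, None, None, None, None]
        ic = np.arange(c)[None, :, None, None, None]
        ib, ic, iz, iy, ix = np.broadcast_arrays(ib, ic, iz, iy, ix)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        np.add.at(dxp, (ib, ic, iz, iy, ix), gy)
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        return dxp[:, :, : x_shape[2], : x_shape[3], : x_shape[4]]


class SpatialDropout3d(Layer):
    """Channel-wise dropout: whole feature maps are zeroed during training."""

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng: Optional[np.random.Generator] = None  # set by the trainer
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        rng = self.rng or np.random.default_rng(0)
        keep = (rng.uniform(size=(x.shape[0], x.shape[1], 1, 1, 1)) >= self.p).astype(np.float32)
        self._mask = keep / (1.0 - self.p)
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        m = self._mask
        self._mask = None
        return gy * m


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, c, d, h, w = self._shape
        return (
            np.broadcast_to(gy[:, :, None, None, None], self._shape) / (d * h * w)
        ).astype(np.float32)


class Linear(Layer):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: Optional[np.random.Generator] = None,
        lr_mult: float = 1.0,
        name: str = "fc",
    ):
        rng = rng or np.random.default_rng(0)
        self.weight = Param(
            f"{name}.weight", glorot_uniform(rng, (c_out, c_in), c_in, c_out), lr_mult=lr_mult
        )
        self.bias = Param(
            f"{name}.bias", np.zeros(c_out, dtype=np.float32), lr_mult=lr_mult, decay=False
        )
        self._x: Optional[np.ndarray] = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        self.weight.grad += gy.T @ x
        self.bias.grad += gy.sum(axis=0)
        return (gy @ self.weight.value).astype(np.float32)


class BasicBlock(Layer):
    """Residual basic block: two 3x3x3 conv+BN with identity or projection skip.

    The projection variant (used when stride > 1 or channel width changes)
    carries a 1x1x1 strided convolution + BN on the shortcut.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        stride: int = 1,
        rng: Optional[np.random.Generator] = None,
        name: str = "block",
    ):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv3d(c_in, c_out, 3, stride=stride, rng=rng, name=f"{name}.conv1")
        self.bn1 = BatchNorm3d(c_out, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv3d(c_out, c_out, 3, stride=1, rng=rng, name=f"{name}.conv2")
        self.bn2 = BatchNorm3d(c_out, name=f"{name}.bn2")
        self.relu_out = ReLU()
        self.projects = stride != 1 or c_in != c_out
        if self.projects:
            self.proj = Conv3d(c_in, c_out, 1, stride=stride, pad=0, rng=rng, name=f"{name}.proj")
            self.proj_bn = BatchNorm3d(c_out, name=f"{name}.proj_bn")

    def params(self) -> list[Param]:
        out = (
            self.conv1.params()
            + self.bn1.params()
            + self.conv2.params()
            + self.bn2.params()
        )
        if self.projects:
            out += self.proj.params() + self.proj_bn.params()
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        if self.projects:
            sc = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            sc = x
        return self.relu_out.forward(y + sc, train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(gy)
        g_branch = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(self.conv2.backward(self.bn2.backward(g)))
            )
        )
        if self.projects:
            g_skip = self.proj.backward(self.proj_bn.backward(g))
        else:
            g_skip = g
        return g_branch + g_skip
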