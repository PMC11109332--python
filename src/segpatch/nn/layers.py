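"""Minimal neural-network layers on numpy arrays, with explicit backprop.

Each layer caches what its backward pass needs during forward. Convolutions
are im2col + GEMM; the column matrix is kept for the weight gradient and the
input gradient is scattered back with a small loop over kernel offsets.
Shapes follow the channel-first convention: (N, C, [Z,] Y, X).
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv", "ReLU", "MaxPool", "GlobalAvgPool", "Linear"]


class Layer:
    """Base class: parameterless layers leave `params`/`grads` empty."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv(Layer):
    """k^dim convolution, stride 1, same (zero) padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        dim: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.cin, self.cout, self.k, self.dim = in_channels, out_channels, kernel, dim
        fan_in = in_channels * kernel**dim
        bound = 1.0 / np.sqrt(fan_in)
        self.W = rng.uniform(-bound, bound, (out_channels, in_channels) + (kernel,) * dim).astype(dtype)
        self.b = rng.uniform(-bound, bound, out_channels).astype(dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.gW, self.gb]
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, d = self.k, self.dim
        p = k // 2
        N, C = x.shape[:2]
        sp = x.shape[2:]
        xp = np.pad(x, ((0, 0), (0, 0)) + ((p, p),) * d)
        win = sliding_window_view(xp, (k,) * d, axis=tuple(range(2, 2 + d)))
        # (N, C, *sp, *k) -> (N, *sp, C, *k) -> (N*prod(sp), C*k^d)
        order = (0,) + tuple(range(2, 2 + d)) + (1,) + tuple(range(2 + d, 2 + 2 * d))
        cols = win.transpose(order).reshape(N * int(np.prod(sp)), C * k**d)
        Wm = self.W.reshape(self.cout, -1)
        out = cols @ Wm.T + self.b
        out = out.reshape((N,) + sp + (self.cout,))
        out = np.moveaxis(out, -1, 1)
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        k, d, p = self.k, self.dim, self.k // 2
        N, C = x_shape[:2]
        sp = x_shape[2:]
        n_pos = int(np.prod(sp))
        gt = np.moveaxis(g, 1, -1).reshape(N * n_pos, self.cout)
        self.gW[...] = (gt.T @ cols).reshape(self.W.shape)
        self.gb[...] = gt.sum(axis=0)
        gcols = (gt @ self.W.reshape(self.cout, -1)).reshape((N,) + sp + (C,) + (k,) * d)
        gxp = np.zeros((N, C) + tuple(s + 2 * p for s in sp), dtype=g.dtype)
        for off in itertools.product(range(k), repeat=d):
            sl = tuple(slice(i, i + s) for i, s in zip(off, sp))
            piece = gcols[(slice(None),) + (slice(None),) * d + (slice(None),) + off]
            gxp[(slice(None), slice(None)) + sl] += np.moveaxis(piece, -1, 1)
        inner = tuple(slice(p, p + s) for s in sp)
        return gxp[(slice(None), slice(None)) + inner]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0)


class MaxPool(Layer):
    """Non-overlapping 2x(2x)2 max pooling; trailing odd rows/cols are dropped."""

    def __init__(self, dim: int) -> None:
        super().__init__()
        self.dim = dim

    def forward(self, x: np.ndarray) -> np.ndarray:
        d = self.dim
        sp = x.shape[2:]
        out_sp = tuple(s // 2 for s in sp)
        trim = (slice(None), slice(None)) + tuple(slice(0, 2 * s) for s in out_sp)
        xt = x[trim]
        inter = sum(((s, 2) for s in out_sp), ())
        xr = xt.reshape(x.shape[:2] + inter)
        wpos = tuple(3 + 2 * i for i in range(d))
        xw = np.moveaxis(xr, wpos, tuple(range(-d, 0)))
        xw = xw.reshape(xw.shape[: 2 + d] + (2**d,))
        idx = np.argmax(xw, axis=-1)
        out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, out_sp)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        idx, x_shape, out_sp = self._cache
        d = self.dim
        gw = np.zeros(g.shape + (2**d,), dtype=g.dtype)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gw = gw.reshape(g.shape + (2,) * d)
        wpos = tuple(3 + 2 * i for i in range(d))
        gr = np.moveaxis(gw, tuple(range(-d, 0)), wpos)
        gx = np.zeros(x_shape, dtype=g.dtype)
        trim = (slice(None), slice(None)) + tuple(slice(0, 2 * s) for s in out_sp)
        gx[trim] = gr.reshape(x_shape[:2] + tuple(2 * s for s in out_sp))
        return gx


class GlobalAvgPool(Layer):
    """Mean over all spatial axes: (N, C, *sp) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        axes = tuple(range(2, x.ndim))
        return x.mean(axis=axes)

    def backward(self, g: np.ndarray) -> np.ndarray:
        shape = self._shape
        S = int(np.prod(shape[2:]))
        return np.broadcast_to(
            g.reshape(g.shape + (1,) * (len(shape) - 2)) / S, shape
        ).astype(g.dtype)


class Linear(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator,
        dtype=np.float32,
        zero_init: bool = False,
    ) -> None:
        super().__init__()
        if zero_init:
            self.W = np.zeros((out_features, in_features), dtype=dtype)
            self.b = np.zeros(out_features, dtype=dtype)
        else:
            bound = 1.0 / np.sqrt(in_features)
            self.W = rng.uniform(-bound, bound, (out_features, in_features)).astype(dtype)
            self.b = rng.uniform(-bound, bound, out_features).astype(dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.gW, self.gb]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW[...] = g.T @ self._x
        self.gb[...] = g.sum(axis=0)
        return g @ self.W
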