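"""Differentiable layers on numpy arrays (NCHW layout).

Each layer caches what its backward pass needs during ``forward`` and
returns the gradient with respect to its input from ``backward``.  All
arithmetic is float64 for reproducibility and easy finite-difference
verification.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """2D convolution ('same' zero padding, square kernel) via im2col."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride = kernel, stride
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.W = Param(w)
        self.b = Param(np.zeros(out_ch))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        k, s, p = self.k, self.stride, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        Ho, Wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B, Ho * Wo, C * k * k
        )
        wm = self.W.value.reshape(self.out_ch, -1)
        out = cols @ wm.T + self.b.value
        self._cache = (x.shape, xp.shape, cols, Ho, Wo)
        return np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(B, self.out_ch, Ho, Wo)

    def backward(self, g: np.ndarray) -> np.ndarray:
        (B, C, H, W), xp_shape, cols, Ho, Wo = self._cache
        k, s, p = self.k, self.stride, self.k // 2
        gm = np.ascontiguousarray(g.reshape(B, self.out_ch, Ho * Wo).transpose(0, 2, 1))
        self.W.grad += np.einsum("blo,blk->ok", gm, cols).reshape(self.W.value.shape)
        self.b.grad += g.sum(axis=(0, 2, 3))
        wm = self.W.value.reshape(self.out_ch, -1)
        dcols = gm @ wm  # (B, L, C*k*k)
        dwin = dcols.reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((B, C) + xp_shape[2:])
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += dwin[:, :, :, :, i, j]
        return dxp[:, :, p : p + H, p : p + W]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0)


class PixelShuffle(Layer):
    """Rearrange (B, C*r^2, H, W) -> (B, C, H*r, W*r) (subpixel upsampling)."""

    def __init__(self, factor: int):
        self.r = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, Cr2, H, W = x.shape
        r = self.r
        if Cr2 % (r * r):
            raise ValueError(f"{Cr2} channels not divisible by {r}^2")
        C = Cr2 // (r * r)
        self._in_shape = x.shape
        out = x.reshape(B, C, r, r, H, W).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(out).reshape(B, C, H * r, W * r)

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, Cr2, H, W = self._in_shape
        r = self.r
        C = Cr2 // (r * r)
        g = g.reshape(B, C, H, r, W, r).transpose(0, 1, 3, 5, 2, 4)
        return np.ascontiguousarray(g).reshape(B, Cr2, H, W)


class BoxBlur(Layer):
    """Depthwise normalized box ('zero-order hold') blur with reflect padding.

    Applied after each subpixel layer with kernel width equal to that stage's
    upsampling factor to suppress checkerboard artifacts.  The kernel sums to
    one, so constant inputs (and means of any input, up to boundary effects)
    are preserved.
    """

    def __init__(self, width: int):
        if width < 1:
            raise ValueError("width must be >= 1")
        self.k = width
        self.pl = (width - 1) // 2
        self.pr = width // 2

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        if k == 1:
            return x
        self._in_shape = x.shape
        xp = np.pad(
            x, ((0, 0), (0, 0), (self.pl, self.pr), (self.pl, self.pr)), mode="reflect"
        )
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        return win.mean(axis=(-2, -1))

    def backward(self, g: np.ndarray) -> np.ndarray:
        k = self.k
        if k == 1:
            return g
        B, C, H, W = self._in_shape
        inv = 1.0 / (k * k)
        dxp = np.zeros((B, C, H + k - 1, W + k - 1))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + H, j : j + W] += g * inv
        return _reflect_pad_backward(dxp, H, W, self.pl, self.pr)


def _reflect_pad_backward(dxp: np.ndarray, H: int, W: int, pl: int, pr: int) -> np.ndarray:
    """Fold gradients of a reflect-padded array back onto the unpadded one."""
    dx = dxp[:, :, pl : pl + H, pl : pl + W].copy()  # core region
    # rows
    for t in range(pl):
        dx[:, :, pl - t, :] += dxp[:, :, t, pl : pl + W]
    for t in range(pr):
        dx[:, :, H - 2 - t, :] += dxp[:, :, pl + H + t, pl : pl + W]
    # columns (including corner contributions already folded into rows above
    # would double count, so fold columns on the row-folded array)
    col = np.zeros_like(dx)
    for t in range(pl):
        col[:, :, :, pl - t] += _fold_rows(dxp[:, :, :, t], H, pl, pr)
    for t in range(pr):
        col[:, :, :, W - 2 - t] += _fold_rows(dxp[:, :, :, pl + W + t], H, pl, pr)
    return dx + col


def _fold_rows(strip: np.ndarray, H: int, pl: int, pr: int) -> np.ndarray:
    """Fold the row padding of one padded column strip (B, C, H+k-1)."""
    out = strip[:, :, pl : pl + H].copy()
    for t in range(pl):
        out[:, :, pl - t] += strip[:, :, t]
    for t in range(pr):
        out[:, :, H - 2 - t] += strip[:, :, pl + H + t]
    return out
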