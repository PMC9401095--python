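"""Minimal NumPy neural-network layers with explicit backward passes.

All layers operate on NCHW batches (or (N, D) for dense layers), keep their
parameters in an ordered ``params`` dict and accumulate gradients of the same
shapes in ``grads``.  Each layer instance is used at most once per forward
pass, so the forward cache is a plain attribute.

Convolutions use "same" padding: for stride ``s`` the output spatial size is
``ceil(in / s)``; when the total padding is odd the extra pixel goes to the
right/bottom.  im2col matrices are built in strips of output rows so peak
memory stays bounded for large feature maps.
"""

from __future__ import annotations

import math
from collections import OrderedDict

import numpy as np

# cap on the size (in float32 elements) of a single im2col strip
_COL_BUDGET = 16_000_000


def same_pad(size: int, kernel: int, stride: int) -> tuple[int, int]:
    """(before, after) padding so that output size is ceil(size/stride)."""
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    before = total // 2
    return before, total - before


class Module:
    """Base class: parameter/grad bookkeeping."""

    def __init__(self) -> None:
        self.params: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self.grads: "OrderedDict[str, np.ndarray]" = OrderedDict()

    def add_param(self, name: str, value: np.ndarray) -> None:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def cast(self, dtype) -> None:
        """Convert parameters/grads to ``dtype`` (rebinds the arrays).
        Composite modules that alias child parameters must override."""
        for k in list(self.params):
            self.params[k] = self.params[k].astype(dtype)
            self.grads[k] = self.grads[k].astype(dtype)

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    """Same-padded 2-D convolution, weight shape (c_out, c_in*k*k)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        rng = rng or np.random.default_rng(0)
        self.add_param("W", _he_init(rng, c_in * kernel * kernel,
                                     (c_out, c_in * kernel * kernel)))
        self.add_param("b", np.zeros(c_out, dtype=np.float32))

    # -- helpers -----------------------------------------------------------
    def _pad(self, x: np.ndarray) -> np.ndarray:
        _, _, h, w = x.shape
        ph = same_pad(h, self.k, self.stride)
        pw = same_pad(w, self.k, self.stride)
        if ph == (0, 0) and pw == (0, 0):
            return x
        return np.pad(x, ((0, 0), (0, 0), ph, pw))

    def _cols(self, xp: np.ndarray, r0: int, r1: int, ow: int) -> np.ndarray:
        """im2col for output rows [r0, r1); result (N, C*k*k, (r1-r0)*ow)."""
        n, c, _, _ = xp.shape
        k, s = self.k, self.stride
        oh = r1 - r0
        cols = np.empty((n, c, k, k, oh, ow), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, r0 * s + i: r0 * s + i + s * oh: s,
                                      j: j + s * ow: s]
        return cols.reshape(n, c * k * k, oh * ow)

    def _strip_rows(self, n: int, ow: int) -> int:
        per_row = n * self.c_in * self.k * self.k * ow
        return max(1, _COL_BUDGET // max(per_row, 1))

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        oh = -(-h // self.stride)
        ow = -(-w // self.stride)
        xp = self._pad(x)
        self._cache = (x.shape, xp)
        w_mat = self.params["W"]
        out = np.empty((n, self.c_out, oh, ow), dtype=x.dtype)
        strip = self._strip_rows(n, ow)
        for r0 in range(0, oh, strip):
            r1 = min(r0 + strip, oh)
            cols = self._cols(xp, r0, r1, ow)
            o = np.matmul(w_mat[None], cols)
            out[:, :, r0:r1] = o.reshape(n, self.c_out, r1 - r0, ow)
        out += self.params["b"][None, :, None, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, xp = self._cache
        n, _, h, w = x_shape
        _, _, oh, ow = dout.shape
        k, s = self.k, self.stride
        w_mat = self.params["W"]
        dxp = np.zeros_like(xp)
        dW = self.grads["W"]
        strip = self._strip_rows(n, ow)
        for r0 in range(0, oh, strip):
            r1 = min(r0 + strip, oh)
            cols = self._cols(xp, r0, r1, ow)
            do = np.ascontiguousarray(dout[:, :, r0:r1].reshape(n, self.c_out, -1))
            dW += np.matmul(do, cols.transpose(0, 2, 1)).sum(axis=0)
            dcols = np.matmul(w_mat.T[None], do)
            dcols = dcols.reshape(n, -1, k, k, r1 - r0, ow)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, r0 * s + i: r0 * s + i + s * (r1 - r0): s,
                        j: j + s * ow: s] += dcols[:, :, i, j]
        self.grads["b"] += dout.sum(axis=(0, 2, 3))
        ph = same_pad(h, k, s)[0]
        pw = same_pad(w, k, s)[0]
        return dxp[:, :, ph: ph + h, pw: pw + w]


class DepthwiseConv2d(Module):
    """Per-channel (multiplier 1) same-padded convolution, stride 1."""

    def __init__(self, channels: int, kernel: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.channels, self.k = channels, kernel
        rng = rng or np.random.default_rng(0)
        self.add_param("W", _he_init(rng, kernel * kernel,
                                     (channels, kernel * kernel)))
        self.add_param("b", np.zeros(channels, dtype=np.float32))

    def _cols(self, xp: np.ndarray, h: int, w: int) -> np.ndarray:
        n, c = xp.shape[:2]
        k = self.k
        cols = np.empty((n, c, k * k, h, w), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i * k + j] = xp[:, :, i: i + h, j: j + w]
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        pb, pa = same_pad(h, self.k, 1)
        qb, qa = same_pad(w, self.k, 1)
        xp = np.pad(x, ((0, 0), (0, 0), (pb, pa), (qb, qa)))
        cols = self._cols(xp, h, w)
        self._cache = (x.shape, cols, (pb, qb))
        out = np.einsum("nckhw,ck->nchw", cols, self.params["W"], optimize=True)
        out += self.params["b"][None, :, None, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, cols, (pb, qb) = self._cache
        n, c, h, w = x_shape
        k = self.k
        self.grads["W"] += np.einsum("nchw,nckhw->ck", dout, cols, optimize=True)
        self.grads["b"] += dout.sum(axis=(0, 2, 3))
        dcols = np.einsum("nchw,ck->nckhw", dout, self.params["W"], optimize=True)
        ph = same_pad(h, k, 1)
        pw = same_pad(w, k, 1)
        dxp = np.zeros((n, c, h + sum(ph), w + sum(pw)), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i: i + h, j: j + w] += dcols[:, :, i * k + j]
        return dxp[:, :, pb: pb + h, qb: qb + w]


class ConvTranspose2dDouble(Module):
    """Learnable upsampling contracted to exactly double H and W.

    Implemented as zero-dilation of the input to (2H, 2W) followed by a
    stride-1 same-padded convolution, which realises a stride-2 kernel-3
    transposed convolution with output_padding 1.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.core = Conv2d(c_in, c_out, kernel, stride=1, rng=rng)
        self.params = self.core.params
        self.grads = self.core.grads

    def cast(self, dtype) -> None:
        self.core.cast(dtype)
        self.params = self.core.params
        self.grads = self.core.grads

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        z = np.zeros((n, c, 2 * h, 2 * w), dtype=x.dtype)
        z[:, :, ::2, ::2] = x
        return self.core.forward(z)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = self.core.backward(dout)
        return dz[:, :, ::2, ::2]


class Dense(Module):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        rng = rng or np.random.default_rng(0)
        self.add_param("W", _he_init(rng, n_in, (n_in, n_out)))
        self.add_param("b", np.zeros(n_out, dtype=np.float32))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["W"] += x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.1) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x >= 0
        return np.where(self._cache, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._cache, dout, self.slope * dout)


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        self._cache = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        s = self._cache
        return dout * s * (1.0 - s)


class MaxPool2x2(Module):
    """2x2 window, stride 2, no padding; requires even H and W."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max-pool needs even spatial dims, got {h}x{w}")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2)
        win = win.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = win.argmax(axis=-1)
        self._cache = (x.shape, idx)
        return np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, idx = self._cache
        n, c, h, w = x_shape
        dwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
        dwin = dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dwin.reshape(n, c, h, w)


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) channel-wise spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._cache
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               (n, c, h, w)).astype(dout.dtype)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
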