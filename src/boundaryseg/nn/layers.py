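"""Minimal CPU layers with explicit forward/backward passes.

Data layout is NCHW float32.  Convolutions use im2col + GEMM; the input
gradient is computed as a full correlation with the spatially flipped,
channel-transposed kernel (another GEMM), so no scatter-add is needed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "MaxPool2", "UpsampleNearest", "sigmoid", "Adam"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*k*k) patch matrix for a stride-1 same conv."""
    b, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (B, C, H, W, k, k) -> (B, H, W, C, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)
    return np.ascontiguousarray(cols)


class Conv2d:
    """Stride-1, same-padding convolution (kernel 1 or odd)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 zero_init: bool = False):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        if zero_init:
            self.W = np.zeros((c_out, c_in, k, k), dtype=np.float32)
        else:
            std = np.sqrt(2.0 / fan_in)
            self.W = rng.normal(0.0, std, size=(c_out, c_in, k, k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        cols = _im2col(x, self.k)
        wmat = self.W.reshape(self.c_out, -1).T  # (C*k*k, c_out)
        out = cols @ wmat + self.b
        self._cache = (cols, x.shape)
        return out.reshape(b, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        b, c, h, w = xshape
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.dW += (dy_mat.T @ cols).reshape(self.W.shape)
        self.db += dy_mat.sum(axis=0)
        # dx = full-correlation of dy with flipped, transposed kernel.
        w_flip = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (c_in, c_out, k, k)
        dy_cols = _im2col(dy, self.k)
        dx = dy_cols @ w_flip.reshape(self.c_in, -1).T
        return dx.reshape(b, h, w, self.c_in).transpose(0, 3, 1, 2)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, np.float32(0.0))


class MaxPool2:
    """2x2 max pooling with stride 2 (exact argmax routing)."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(b, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (b, c, h, w) = self._cache
        dflat = np.zeros((b, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
        dx = dflat.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(b, c, h, w)


class UpsampleNearest:
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, factor: int):
        self.factor = int(factor)

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.factor
        if f == 1:
            return x
        return x.repeat(f, axis=2).repeat(f, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f = self.factor
        if f == 1:
            return dy
        b, c, hf, wf = dy.shape
        return dy.reshape(b, c, hf // f, f, wf // f, f).sum(axis=(3, 5))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam optimiser over (param, grad) array pairs updated in place."""

    def __init__(self, param_grads, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = list(param_grads)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)

    def zero_grad(self):
        for _, g in self.pairs:
            g[...] = 0.0
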