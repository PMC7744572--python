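"""Layers with forward/backward passes on NCHW float32 arrays."""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d", "UpConv2d",
    "ConvBNReLU", "UpConvBNReLU", "softmax_cross_entropy",
]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*k*k) for stride-1 same convolution."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # windows: (B, C, H, W, k, k)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, h * w, c * k * k)
    return np.ascontiguousarray(cols)


def _col2im(cols: np.ndarray, shape, k: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col (scatter-add of window gradients)."""
    b, c, h, w = shape
    xp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols6 = cols.reshape(b, h, w, c, k, k)
    for di in range(k):
        for dj in range(k):
            xp[:, :, di : di + h, dj : dj + w] += cols6[:, :, :, :, di, dj].transpose(
                0, 3, 1, 2
            )
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


class Layer:
    def params(self):
        return []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or 1x1) stride-1 same-padding convolution with bias."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng=None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * k * k))  # He initialization
        self.w = (rng.standard_normal((cout, cin * k * k)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.k = k
        self.cin, self.cout = cin, cout

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x, train=True):
        self._shape = x.shape
        b, c, h, w = x.shape
        if self.k == 1:
            self._cols = x.transpose(0, 2, 3, 1).reshape(b, h * w, c)
        else:
            self._cols = _im2col(x, self.k, self.k // 2)
        out = self._cols @ self.w.T + self.b
        return out.reshape(b, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, g):
        b, _, h, w = self._shape
        gm = g.transpose(0, 2, 3, 1).reshape(b, h * w, self.cout)
        self.gw += np.einsum("bnc,bnk->ck", gm, self._cols, optimize=True)
        self.gb += gm.sum(axis=(0, 1))
        gcols = gm @ self.w
        if self.k == 1:
            gx = gcols.reshape(b, h, w, self.cin).transpose(0, 3, 1, 2)
        else:
            gx = _col2im(gcols, self._shape, self.k, self.k // 2)
        self._cols = None
        return np.ascontiguousarray(gx)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._xhat = (x - mean[None, :, None, None]) * self._istd[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, g):
        n = g.shape[0] * g.shape[2] * g.shape[3]
        self.ggamma += (g * self._xhat).sum(axis=(0, 2, 3))
        self.gbeta += g.sum(axis=(0, 2, 3))
        gxh = g * self.gamma[None, :, None, None]
        mean_g = gxh.mean(axis=(0, 2, 3))
        mean_gx = (gxh * self._xhat).mean(axis=(0, 2, 3))
        gx = (gxh - mean_g[None, :, None, None]
              - self._xhat * mean_gx[None, :, None, None]) * self._istd[None, :, None, None]
        self._xhat = None
        return gx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        out = g * self._mask
        self._mask = None
        return out


class MaxPool2d(Layer):
    """2x2 stride-2 max pooling (even input dims required)."""

    def forward(self, x, train=True):
        b, c, h, w = x.shape
        xv = x.reshape(b, c, h // 2, 2, w // 2, 2)
        out = xv.max(axis=(3, 5))
        self._mask = xv == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, g):
        b, c, h, w = self._shape
        gx = self._mask * g[:, :, :, None, :, None]
        self._mask = None
        return gx.reshape(b, c, h, w)


class UpConv2d(Layer):
    """2x2 stride-2 transposed convolution (non-overlapping up-convolution)."""

    def __init__(self, cin: int, cout: int, rng=None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / cin)
        self.w = (rng.standard_normal((cin, cout, 2, 2)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.cin, self.cout = cin, cout

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x, train=True):
        self._x = x
        b, c, h, w = x.shape
        out = np.einsum("bchw,cdij->bdhiwj", x, self.w, optimize=True)
        out = out.reshape(b, self.cout, 2 * h, 2 * w) + self.b[None, :, None, None]
        return np.ascontiguousarray(out.astype(np.float32))

    def backward(self, g):
        b, d, h2, w2 = g.shape
        g6 = g.reshape(b, d, h2 // 2, 2, w2 // 2, 2)
        self.gw += np.einsum("bchw,bdhiwj->cdij", self._x, g6, optimize=True)
        self.gb += g.sum(axis=(0, 2, 3))
        gx = np.einsum("bdhiwj,cdij->bchw", g6, self.w, optimize=True)
        self._x = None
        return np.ascontiguousarray(gx.astype(np.float32))


class ConvBNReLU(Layer):
    """One network layer: convolution -> batch norm -> ReLU."""

    def __init__(self, cin, cout, k=3, rng=None):
        self.conv = Conv2d(cin, cout, k=k, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.relu = ReLU()
        self.cout = cout

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, train=True):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, g):
        return self.conv.backward(self.bn.backward(self.relu.backward(g)))


class UpConvBNReLU(Layer):
    """Up-convolution network layer: transposed conv -> batch norm -> ReLU."""

    def __init__(self, cin, cout, rng=None):
        self.up = UpConv2d(cin, cout, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.relu = ReLU()
        self.cout = cout

    def params(self):
        return self.up.params() + self.bn.params()

    def forward(self, x, train=True):
        return self.relu.forward(self.bn.forward(self.up.forward(x, train), train), train)

    def backward(self, g):
        return self.up.backward(self.bn.backward(self.relu.backward(g)))


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean pixel-wise cross entropy.

    logits: (B, C, H, W); labels: (B, H, W) int.  Returns (loss, grad).
    """
    b, c, h, w = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = b * h * w
    onehot_p = np.take_along_axis(p, labels[:, None, :, :], axis=1)[:, 0]
    loss = float(-np.log(np.maximum(onehot_p, 1e-12)).mean())
    grad = p.copy()
    bidx = np.arange(b)[:, None, None]
    hidx = np.arange(h)[None, :, None]
    widx = np.arange(w)[None, None, :]
    grad[bidx, labels, hidx, widx] -= 1.0
    grad /= n
    return loss, grad.astype(np.float32)
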