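"""Minimal convolutional network primitives on numpy.

im2col-based 2-D convolution with explicit backward passes, 2x2 max pooling,
dense layers, softmax cross-entropy and Adam/SGD updates — just enough to
express the two small networks in this package (the fusion network and the
classifier) deterministically on a CPU.  Arrays are NCHW ``float32`` unless
noted; all randomness is injected through explicit generators.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv2d",
    "conv2d_backward",
    "maxpool2",
    "maxpool2_backward",
    "relu",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N,C,H,W) -> (N, oh*ow, C*kh*kw) patch matrix for valid convolution."""
    n, c, h, w = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    # win: (N, C, oh, ow, kh, kw) -> (N, oh, ow, C, kh, kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(n, oh * ow, c * kh * kw)


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, padding: int = 0):
    """Cross-correlation of NCHW input with (F,C,kh,kw) kernels.

    Returns ``(y, cache)``; the cache feeds :func:`conv2d_backward`.
    """
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    n, c, h, wd = x.shape
    f, _, kh, kw = w.shape
    oh, ow = h - kh + 1, wd - kw + 1
    cols = _im2col(x, kh, kw)
    k = cols.shape[-1]
    y = cols.reshape(n * oh * ow, k) @ w.reshape(f, k).T + b
    y = y.reshape(n, oh * ow, f).transpose(0, 2, 1).reshape(n, f, oh, ow)
    return y, (cols, x.shape, w.shape, padding)


def conv2d_backward(dy: np.ndarray, w: np.ndarray, cache, need_dx: bool = True):
    """Gradients of conv2d: returns (dx, dw, db); dx is None if not needed."""
    cols, xshape, wshape, padding = cache
    n, f, oh, ow = dy.shape
    _, c, kh, kw = wshape
    p = oh * ow
    k = cols.shape[-1]
    dyf = np.ascontiguousarray(dy.reshape(n, f, p).transpose(0, 2, 1)).reshape(n * p, f)
    dw = (dyf.T @ cols.reshape(n * p, k)).reshape(wshape)
    db = dy.sum(axis=(0, 2, 3))
    dx = None
    if need_dx:
        dcols = dyf @ w.reshape(f, k)  # (N*P, C*kh*kw)
        dcols = dcols.reshape(n, oh, ow, c, kh, kw)
        dxp = np.zeros(xshape, dtype=dy.dtype)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + oh, j : j + ow] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        if padding:
            dx = dxp[:, :, padding:-padding, padding:-padding]
        else:
            dx = dxp
    return dx, dw, db


def maxpool2(x: np.ndarray):
    """2x2 max pooling, stride 2, valid (odd trailing row/column dropped)."""
    n, c, h, w = x.shape
    h2, w2 = (h // 2) * 2, (w // 2) * 2
    xc = x[:, :, :h2, :w2].reshape(n, c, h2 // 2, 2, w2 // 2, 2)
    xf = xc.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2 // 2, w2 // 2, 4)
    idx = xf.argmax(axis=-1)
    y = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]
    return y, (x.shape, idx)


def maxpool2_backward(dy: np.ndarray, cache) -> np.ndarray:
    xshape, idx = cache
    n, c, h, w = xshape
    h2, w2 = (h // 2) * 2, (w // 2) * 2
    dxf = np.zeros((n, c, h2 // 2, w2 // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dxf, idx[..., None], dy[..., None], axis=-1)
    dxc = dxf.reshape(n, c, h2 // 2, w2 // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    dx = np.zeros(xshape, dtype=dy.dtype)
    dx[:, :, :h2, :w2] = dxc.reshape(n, c, h2, w2)
    return dx


def sconv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, padding: int = 0):
    """Shift-accumulation convolution for a single CHW image.

    Mathematically identical to :func:`conv2d` on a batch of one, but avoids
    the im2col patch copy: for each kernel tap (i, j) a (F, C) x (C, H*W)
    product is accumulated.  Preferable when C*kh*kw is large relative to
    the batch (the fusion network's case).
    """
    if padding:
        x = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    c, h, wd = x.shape
    f, _, kh, kw = w.shape
    oh, ow = h - kh + 1, wd - kw + 1
    y = np.zeros((f, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            y += np.tensordot(w[:, :, i, j], x[:, i : i + oh, j : j + ow], axes=1)
    y += b[:, None, None]
    return y, x  # cache = padded input


def sconv2d_backward(dy: np.ndarray, xpad: np.ndarray, w: np.ndarray, padding: int, need_dx: bool = True):
    """Gradients of :func:`sconv2d`: returns (dx, dw, db)."""
    f, _, kh, kw = w.shape
    _, oh, ow = dy.shape
    dw = np.empty_like(w)
    dyf = dy.reshape(f, -1)
    dxp = np.zeros_like(xpad) if need_dx else None
    for i in range(kh):
        for j in range(kw):
            patch = xpad[:, i : i + oh, j : j + ow]
            dw[:, :, i, j] = dyf @ patch.reshape(patch.shape[0], -1).T
            if need_dx:
                dxp[:, i : i + oh, j : j + ow] += np.tensordot(w[:, :, i, j].T, dy, axes=1)
    db = dy.sum(axis=(1, 2))
    dx = None
    if need_dx:
        dx = dxp[:, padding:-padding, padding:-padding] if padding else dxp
    return dx, dw, db


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class Adam:
    """Adam updates over a dict of named parameter arrays (in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
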