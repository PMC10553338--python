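"""Minimal numpy neural-network layers with manual backpropagation.

Only what the U-Net needs: stride-1 same-padding 3x3/1x1 convolutions
(im2col forward; the input gradient is computed as a convolution with the
flipped, transposed kernels, exact for zero padding), ReLU, 2x2 max pooling,
nearest-neighbor x2 upsampling, channel concatenation, and Adam.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["conv2d", "conv2d_backward", "relu", "relu_backward",
           "maxpool2", "maxpool2_backward", "upsample2",
           "upsample2_backward", "Adam", "he_init"]


def he_init(rng, c_out, c_in, k):
    scale = np.sqrt(2.0 / (c_in * k * k))
    return rng.standard_normal((c_out, c_in, k, k)) * scale


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*k*k) patches with zero same-padding."""
    b, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,C,H,W,k,k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b, h * w, c * k * k)


def conv2d(x: np.ndarray, W: np.ndarray, bias: np.ndarray):
    """Same-padding stride-1 convolution; returns (out, cache)."""
    b, c, h, w = x.shape
    c_out, c_in, k, _ = W.shape
    cols = _im2col(x, k)
    out = cols @ W.reshape(c_out, -1).T + bias
    out = out.transpose(0, 2, 1).reshape(b, c_out, h, w)
    return out, (x, cols, W.shape)


def conv2d_backward(dout: np.ndarray, cache, W: np.ndarray):
    """Gradients (dx, dW, db) of :func:`conv2d`."""
    x, cols, wshape = cache
    b, c, h, w = x.shape
    c_out, c_in, k, _ = wshape
    dout2 = dout.reshape(b, c_out, h * w).transpose(0, 2, 1)  # (B, HW, Cout)
    dW = np.tensordot(dout2, cols, axes=([0, 1], [0, 1])).reshape(wshape)
    db = dout2.sum(axis=(0, 1))
    # input gradient = conv of dout with flipped, channel-transposed kernels
    Wt = W.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
    dcols = _im2col(dout, k)
    dx = dcols @ Wt.reshape(c_in, -1).T
    dx = dx.transpose(0, 2, 1).reshape(b, c_in, h, w)
    return dx, dW, db


def relu(x):
    return np.maximum(x, 0.0)


def relu_backward(dout, x):
    return dout * (x > 0)


def maxpool2(x: np.ndarray):
    b, c, h, w = x.shape
    xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(b, c, h // 2, w // 2, 4)
    am = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, am[..., None], axis=-1)[..., 0]
    return out, (am, x.shape)


def maxpool2_backward(dout: np.ndarray, cache):
    am, shape = cache
    b, c, h, w = shape
    dxr = np.zeros((b, c, h // 2, w // 2, 4))
    np.put_along_axis(dxr, am[..., None], dout[..., None], axis=-1)
    dx = dxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dx.reshape(b, c, h, w)


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dout: np.ndarray) -> np.ndarray:
    b, c, h, w = dout.shape
    return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
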