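"""Minimal CNN engine with explicit forward/backward passes.

This module implements exactly the layer set the plane-detection networks
need — 2-D convolution, batch normalisation, rectification, 2x2 max pooling —
with hand-written backward passes.  Owning the backward pass is the point:
the weakly supervised localisation mechanism modifies backpropagation at
every rectifier (guided gating), and the saliency computation needs to seed
the backward pass with arbitrary error fields at the class-score-map layer,
neither of which is expressible as a plain gradient of a scalar loss.

Conventions
-----------
* Activations are ``(N, C, H, W)`` float arrays (``float32`` by default).
* ``forward(x, train=...)`` caches what ``backward`` needs; ``backward(gy,
  guided=...)`` returns the error w.r.t. the layer input and, when the
  forward pass ran with ``train=True``, accumulates parameter gradients in
  ``layer.grads``.
* Guided gating zeroes the backward error at a rectifier wherever the
  forward input or the incoming error is non-positive.  Convolutions and
  batch normalisation always propagate ordinary (exact) gradients.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "he_init",
]


def he_init(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator,
            dtype=np.float32) -> np.ndarray:
    """Variance-scaling (He) normal initialisation for rectified nets."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Layer:
    """Base class; parameter-free layers inherit the empty dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray, guided: bool = False) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


def _shift_conv(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Stride-1 cross-correlation as a sum of k*k shifted channel matmuls.

    Decomposing over kernel taps keeps the per-tap operand a cheap strided
    slice (no im2col gather), which dominates throughput at the channel
    widths used here.  ``x`` is ``(N, C, H, W)``, ``w`` ``(Co, C, k, k)``.
    """
    co, c, k, _ = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, _, hp, wp = x.shape
    ho, wo = hp - k + 1, wp - k + 1
    y = None
    for di in range(k):
        for dj in range(k):
            xs = x[:, :, di:di + ho, dj:dj + wo]
            # (N,C,Ho,Wo) x (Co,C) -> (N,Co,Ho,Wo)
            t = np.tensordot(w[:, :, di, dj], xs, axes=([1], [1]))
            t = t.transpose(1, 0, 2, 3)
            y = t if y is None else y + t
    return y


class Conv2d(Layer):
    """Stride-1 2-D convolution (cross-correlation) with symmetric padding.

    3x3 kernels use ``pad=1`` ("same" output); the 1x1 adaptation layers use
    ``pad=0``.  Larger odd kernels with ``pad=(k-1)//2`` also work.
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, ksize
        self.pad = (ksize - 1) // 2 if pad is None else pad
        rng = np.random.default_rng() if rng is None else rng
        fan_in = in_ch * ksize * ksize
        self.params = {
            "w": he_init((out_ch, in_ch, ksize, ksize), fan_in, rng, dtype),
            "b": np.zeros(out_ch, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._xpad = None
        self._train = False

    def forward(self, x, train=False):
        w, b = self.params["w"], self.params["b"]
        y = _shift_conv(x, w, self.pad)
        y += b[None, :, None, None]
        self._train = train
        if train:
            p = self.pad
            self._xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p \
                else x
        return y

    def backward(self, gy, guided=False):
        w = self.params["w"]
        k, pad = self.k, self.pad
        if self._train:
            xp = self._xpad
            ho, wo = gy.shape[2], gy.shape[3]
            gw = np.empty_like(self.grads["w"])
            for di in range(k):
                for dj in range(k):
                    xs = xp[:, :, di:di + ho, dj:dj + wo]
                    gw[:, :, di, dj] = np.tensordot(
                        gy, xs, axes=([0, 2, 3], [0, 2, 3]))
            self.grads["w"] += gw
            self.grads["b"] += gy.sum(axis=(0, 2, 3))
        # Error w.r.t. input: full correlation with the flipped, transposed
        # kernel (exact adjoint of the forward map).
        wt = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        return _shift_conv(gy, wt, k - 1 - pad)


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with learned scale/shift.

    Training mode normalises by mini-batch statistics over (N, H, W) and
    updates exponential running estimates; inference mode uses the running
    estimates, making the layer a fixed affine map (its backward is then the
    exact gradient of that affine map, as guided backpropagation requires).
    """

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {
            "gamma": np.ones(ch, dtype=dtype),
            "beta": np.zeros(ch, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self._cache = None

    def forward(self, x, train=False):
        gamma = self.params["gamma"][None, :, None, None]
        beta = self.params["beta"][None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train)
        return gamma * xhat + beta

    def backward(self, gy, guided=False):
        xhat, inv_std, train = self._cache
        gamma = self.params["gamma"]
        if train:
            m = gy.shape[0] * gy.shape[2] * gy.shape[3]
            ggamma = (gy * xhat).sum(axis=(0, 2, 3))
            gbeta = gy.sum(axis=(0, 2, 3))
            self.grads["gamma"] += ggamma
            self.grads["beta"] += gbeta
            gx = (gamma * inv_std)[None, :, None, None] / m * (
                m * gy
                - gbeta[None, :, None, None]
                - xhat * ggamma[None, :, None, None]
            )
            return gx
        return gy * (gamma * inv_std)[None, :, None, None]


class ReLU(Layer):
    """Rectifier; the locus of guided gating during backpropagation."""

    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, gy, guided=False):
        gx = np.where(self._mask, gy, 0)
        if guided:
            gx = np.where(gx > 0, gx, 0)
        return gx


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2; first-index tie-break in the backward."""

    def __init__(self) -> None:
        super().__init__()
        self._idx = None
        self._shape = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(
                f"max pooling needs even spatial dims, got {h}x{w}")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        self._idx = win.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy, guided=False):
        _, c, h, w = self._shape
        n = gy.shape[0]  # may exceed the forward batch (broadcast seeds)
        idx = np.broadcast_to(self._idx, gy.shape)
        grid = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(grid, idx[..., None], gy[..., None], axis=-1)
        gx = grid.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(gx.reshape(n, c, h, w))
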