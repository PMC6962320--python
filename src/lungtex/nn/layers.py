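"""Layers with explicit forward/backward passes.

Conventions: 2D feature maps are (N, C, H, W); 3D maps are (N, C, D, H, W)
with D the thin axial-slice axis. Convolutions are 3x3 (or 3x3x3),
stride 1, 'same' zero padding. Pooling is 2x2 stride 2 over (H, W) only,
preserving the thin D extent of 3D slabs. Weight tensors carry He-uniform
initialization; biases start at zero.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np


def he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: subclasses fill ``params``/``grads`` dicts and declare
    which parameter keys are weights (subject to L2 decay)."""

    weight_keys: Tuple[str, ...] = ()

    def __init__(self):
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool,
                rng: Optional[np.random.Generator]) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _conv_nd(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Same-padded correlation of (N, C, *spatial) with (O, C, *kernel).

    Implemented as one GEMM per kernel offset (shift-and-matmul), which
    keeps every operand contiguous and small instead of materializing the
    full sliding-window tensor.
    """
    from itertools import product

    kshape = W.shape[2:]
    pads = [k // 2 for k in kshape]
    N, C = x.shape[:2]
    O = W.shape[0]
    spatial = x.shape[2:]
    S = int(np.prod(spatial))
    xp = np.pad(x, [(0, 0), (0, 0)] + [(p, p) for p in pads])
    out = np.zeros((N, O, S))
    for off in product(*[range(k) for k in kshape]):
        sl = tuple(slice(o, o + s) for o, s in zip(off, spatial))
        xs = np.ascontiguousarray(xp[(slice(None), slice(None)) + sl]
                                  ).reshape(N, C, S)
        out += np.matmul(W[(slice(None), slice(None)) + off], xs)
    return out.reshape((N, O) + spatial)


def _conv_nd_weight_grad(x: np.ndarray, dout: np.ndarray,
                         kshape: tuple) -> np.ndarray:
    """Gradient of _conv_nd with respect to W."""
    from itertools import product

    pads = [k // 2 for k in kshape]
    N, C = x.shape[:2]
    O = dout.shape[1]
    spatial = x.shape[2:]
    S = int(np.prod(spatial))
    xp = np.pad(x, [(0, 0), (0, 0)] + [(p, p) for p in pads])
    do = dout.reshape(N, O, S)
    dW = np.zeros((O, C) + tuple(kshape))
    for off in product(*[range(k) for k in kshape]):
        sl = tuple(slice(o, o + s) for o, s in zip(off, spatial))
        xs = np.ascontiguousarray(xp[(slice(None), slice(None)) + sl]
                                  ).reshape(N, C, S)
        # (O,C) = sum_n do[n] @ xs[n].T
        dW[(slice(None), slice(None)) + off] = np.einsum(
            "nos,ncs->oc", do, xs, optimize=True)
    return dW


class _ConvND(Layer):
    weight_keys = ("W",)

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 ndim: int, ksize: int = 3):
        super().__init__()
        self.ksize = ksize
        self.ndim = ndim
        fan_in = in_ch * ksize ** ndim
        self.params["W"] = he_uniform(
            rng, (out_ch, in_ch) + (ksize,) * ndim, fan_in)
        self.params["b"] = np.zeros(out_ch)

    def forward(self, x, training, rng):
        self._x = x
        b = self.params["b"].reshape((1, -1) + (1,) * self.ndim)
        return _conv_nd(x, self.params["W"]) + b

    def backward(self, dout):
        x, W = self._x, self.params["W"]
        self.grads["W"] = _conv_nd_weight_grad(x, dout, W.shape[2:])
        self.grads["b"] = dout.sum(axis=(0,) + tuple(range(2, dout.ndim)))
        # dx = correlation of dout with the flipped, in/out-transposed kernel
        flip = (slice(None), slice(None)) + (slice(None, None, -1),) * self.ndim
        Wt = W[flip].transpose((1, 0) + tuple(range(2, W.ndim)))
        return _conv_nd(dout, Wt)


class Conv2D(_ConvND):
    def __init__(self, in_ch, out_ch, rng, ksize: int = 3):
        super().__init__(in_ch, out_ch, rng, ndim=2, ksize=ksize)


class Conv3D(_ConvND):
    def __init__(self, in_ch, out_ch, rng, ksize: int = 3):
        super().__init__(in_ch, out_ch, rng, ndim=3, ksize=ksize)


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2x2(Layer):
    """2x2 stride-2 max pooling over the last two axes (H, W).

    Works for both (N, C, H, W) and (N, C, D, H, W); H and W must be even.
    Gradient at ties is split evenly among the tied positions, which keeps
    the backward pass deterministic.
    """

    def forward(self, x, training, rng):
        *lead, H, W = x.shape
        xr = x.reshape(*lead, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(-3, -1))
        mask = (xr == out[..., :, None, :, None])
        self._mask = mask / mask.sum(axis=(-3, -1), keepdims=True)
        self._in_shape = x.shape
        return out

    def backward(self, dout):
        d = dout[..., :, None, :, None] * self._mask
        return d.reshape(self._in_shape)


class BatchNorm(Layer):
    """Per-channel batch normalization (channel axis 1), with running
    statistics for inference mode."""

    weight_keys = ()  # gamma/beta are excluded from L2 decay

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(n_ch)
        self.params["beta"] = np.zeros(n_ch)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)

    def _axes(self, x):
        return (0,) + tuple(range(2, x.ndim))

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, training, rng):
        axes = self._axes(x)
        shp = self._shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shp)) / self._std.reshape(shp)
        self._training = training
        self._n = x.size // x.shape[1]
        return (self.params["gamma"].reshape(shp) * self._xhat
                + self.params["beta"].reshape(shp))

    def backward(self, dout):
        axes = self._axes(dout)
        shp = self._shape(dout)
        xhat = self._xhat
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"].reshape(shp)
        dxhat = dout * g
        if not self._training:
            return dxhat / self._std.reshape(shp)
        n = self._n
        return (dxhat - dxhat.mean(axis=axes).reshape(shp)
                - xhat * (dxhat * xhat).mean(axis=axes).reshape(shp)
                ) / self._std.reshape(shp)


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class GlobalAvgPool(Layer):
    """Average each channel over all spatial axes -> (N, C)."""

    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dout):
        shp = self._shape
        n_spatial = int(np.prod(shp[2:]))
        expand = dout.reshape(shp[0], shp[1], *([1] * (len(shp) - 2)))
        return np.broadcast_to(expand / n_spatial, shp).copy()


class Dense(Layer):
    weight_keys = ("W",)

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = he_uniform(rng, (n_in, n_out), n_in)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; active only in training mode, seeded via the rng
    threaded through ``forward``."""

    def __init__(self, p: float = 0.5):
        super().__init__()
        self.p = p

    def forward(self, x, training, rng):
        if not training or self.p <= 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode requires an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential:
    """A chain of layers with optional gradient capture at one layer
    boundary (used by Grad-CAM)."""

    def __init__(self, layers: List[Layer]):
        self.layers = layers

    def forward(self, x, training=False, rng=None):
        for lyr in self.layers:
            x = lyr.forward(x, training, rng)
        return x

    def backward(self, dout, capture_after: Optional[int] = None):
        """Propagate gradients; if ``capture_after`` is an index i, also
        return the gradient with respect to the *output* of layer i."""
        captured = None
        for idx in range(len(self.layers) - 1, -1, -1):
            if capture_after is not None and idx == capture_after:
                captured = dout
            dout = self.layers[idx].backward(dout)
        return dout, captured

    def iter_layers(self):
        return iter(self.layers)
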