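"""Minimal 3D neural-network layers with explicit backpropagation.

Layers operate on arrays of shape ``(N, C, D0, D1, D2)`` (batch, channels,
three spatial axes) in float32.  Each layer caches what it needs during
``forward`` and returns the gradient with respect to its input from
``backward``; parameter gradients are accumulated on the layer itself
(``dW``, ``db``).  Convolutions are expressed as strided-window tensor
contractions so that the heavy lifting happens inside BLAS.

Conventions fixed here and relied on elsewhere:

* "valid" pooling/convolution uses floor division for the output size,
  "same" uses ceil division with TensorFlow-style asymmetric padding
  (extra voxel at the end).
* He initialisation draws kernels from N(0, 2/fan_in), the scheme for
  rectified units; biases start at zero.
* LeakyReLU slope defaults to 0.3.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def _triple(v):
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected scalar or length-3, got {v!r}")
    return t


def same_padding(size: int, kernel: int, stride: int) -> tuple[int, int]:
    """TF-style 'same' padding amounts (before, after) for one axis."""
    out = -(-size // stride)  # ceil
    pad = max((out - 1) * stride + kernel - size, 0)
    return pad // 2, pad - pad // 2


class Layer:
    """Base class; subclasses define forward/backward."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray:
        raise NotImplementedError

    def parameters(self):
        """Yield (attribute-name, array) pairs of trainable parameters."""
        return ()

    def gradients(self):
        return ()


class Conv3D(Layer):
    """3D cross-correlation with optional stride and valid/same padding."""

    def __init__(self, in_channels, out_channels, kernel=3, stride=1,
                 padding="valid", rng=None):
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        self.padding = padding
        fan_in = self.in_channels * int(np.prod(self.kernel))
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, std, size=(self.out_channels, self.in_channels,
                                            *self.kernel)).astype(DTYPE)
        self.b = np.zeros(self.out_channels, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._col = None
        self._pads = None
        self._xp_shape = None
        self._out_spatial = None

    def parameters(self):
        return (("W", self.W), ("b", self.b))

    def gradients(self):
        return (("W", self.dW), ("b", self.db))

    def _pad_amounts(self, spatial):
        if self.padding == "valid":
            return tuple((0, 0) for _ in range(3))
        return tuple(same_padding(spatial[i], self.kernel[i], self.stride[i])
                     for i in range(3))

    def forward(self, x, train=False):
        pads = self._pad_amounts(x.shape[2:])
        xp = np.pad(x, ((0, 0), (0, 0), *pads)) if any(sum(p) for p in pads) else x
        s = self.stride
        win = sliding_window_view(xp, self.kernel, axis=(2, 3, 4))
        win = win[:, :, ::s[0], ::s[1], ::s[2]]
        N = x.shape[0]
        out_sp = win.shape[2:5]
        # im2col: one contiguous copy, reused by backward for the weight grad
        col = np.ascontiguousarray(np.moveaxis(win, 1, 4)).reshape(
            N * int(np.prod(out_sp)), -1)
        wmat = self.W.reshape(self.out_channels, -1).T  # (C*K, F)
        y = col @ wmat
        y = np.moveaxis(y.reshape(N, *out_sp, self.out_channels), -1, 1)
        y += self.b[None, :, None, None, None]
        if train:
            self._col = col
            self._pads = pads
            self._xp_shape = xp.shape
            self._out_spatial = out_sp
        return np.ascontiguousarray(y, dtype=DTYPE)

    def backward(self, dy, need_dx=True):
        if self._col is None:
            raise RuntimeError("backward requires a forward pass with train=True")
        k, s = self.kernel, self.stride
        N, F = dy.shape[:2]
        out_sp = dy.shape[2:]
        dy_mat = np.ascontiguousarray(np.moveaxis(dy, 1, -1)).reshape(-1, F)
        dW = self._col.T @ dy_mat  # (C*K, F)
        self.dW = np.ascontiguousarray(
            np.moveaxis(dW.reshape(self.in_channels, *k, F), -1, 0), dtype=DTYPE)
        self.db = dy_mat.sum(axis=0).astype(DTYPE)
        if not need_dx:
            return None
        # scatter per kernel offset: cheap matmuls, no windowed copies
        pads = self._pads
        dxp = np.zeros(self._xp_shape, dtype=DTYPE)
        o0, o1, o2 = out_sp
        for a in range(k[0]):
            for b in range(k[1]):
                for c in range(k[2]):
                    v = self.W[:, :, a, b, c]  # (F, C)
                    tmp = (dy_mat @ v).reshape(N, o0, o1, o2, self.in_channels)
                    dxp[:, :,
                        a:a + s[0] * o0:s[0],
                        b:b + s[1] * o1:s[1],
                        c:c + s[2] * o2:s[2]] += np.moveaxis(tmp, -1, 1)
        sl = tuple(slice(p[0], dxp.shape[2 + i] - p[1]) for i, p in enumerate(pads))
        return np.ascontiguousarray(dxp[:, :, sl[0], sl[1], sl[2]], dtype=DTYPE)

    def output_shape(self, spatial):
        pads = self._pad_amounts(spatial)
        return tuple((spatial[i] + sum(pads[i]) - self.kernel[i]) // self.stride[i] + 1
                     for i in range(3))


class MaxPool3D(Layer):
    """Max pooling; 'valid' floors the output size, 'same' ceils it."""

    NEG = np.array(-np.inf, dtype=DTYPE)

    def __init__(self, pool=2, stride=None, padding="valid"):
        self.pool = _triple(pool)
        self.stride = _triple(stride if stride is not None else pool)
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        self.padding = padding
        self._cache = None

    def _pad_amounts(self, spatial):
        if self.padding == "valid":
            return tuple((0, 0) for _ in range(3))
        return tuple(same_padding(spatial[i], self.pool[i], self.stride[i])
                     for i in range(3))

    def forward(self, x, train=False):
        k, s = self.pool, self.stride
        pads = self._pad_amounts(x.shape[2:])
        xp = (np.pad(x, ((0, 0), (0, 0), *pads), constant_values=self.NEG)
              if any(sum(p) for p in pads) else x)
        win = sliding_window_view(xp, k, axis=(2, 3, 4))[:, :, ::s[0], ::s[1], ::s[2]]
        flat = win.reshape(*win.shape[:5], -1)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (x.shape, xp.shape, pads, idx)
        return np.ascontiguousarray(y, dtype=DTYPE)

    def backward(self, dy, need_dx=True):
        if self._cache is None:
            raise RuntimeError("backward requires a forward pass with train=True")
        xshape, xpshape, pads, idx = self._cache
        k, s = self.pool, self.stride
        N, C = xshape[:2]
        o0, o1, o2 = idx.shape[2:]
        a, b, c = np.unravel_index(idx, k)
        g0 = np.arange(o0)[:, None, None] * s[0]
        g1 = np.arange(o1)[None, :, None] * s[1]
        g2 = np.arange(o2)[None, None, :] * s[2]
        p0, p1, p2 = xpshape[2:]
        sp0 = (g0 + a)
        sp1 = (g1 + b)
        sp2 = (g2 + c)
        nc = (np.arange(N)[:, None, None, None, None] * C +
              np.arange(C)[None, :, None, None, None])
        flat = ((nc * p0 + sp0) * p1 + sp1) * p2 + sp2
        acc = np.bincount(flat.ravel(), weights=dy.ravel().astype(np.float64),
                          minlength=N * C * p0 * p1 * p2)
        dxp = acc.reshape(N, C, p0, p1, p2)
        sl = tuple(slice(p[0], dxp.shape[2 + i] - p[1]) for i, p in enumerate(pads))
        return np.ascontiguousarray(dxp[:, :, sl[0], sl[1], sl[2]], dtype=DTYPE)

    def output_shape(self, spatial):
        pads = self._pad_amounts(spatial)
        return tuple((spatial[i] + sum(pads[i]) - self.pool[i]) // self.stride[i] + 1
                     for i in range(3))


class GlobalAvgPool3D(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy, need_dx=True):
        N, C, d0, d1, d2 = self._shape
        scale = DTYPE(1.0 / (d0 * d1 * d2))
        return np.broadcast_to((dy * scale)[:, :, None, None, None],
                               self._shape).astype(DTYPE)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy, need_dx=True):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features, out_features, rng=None):
        self.in_features = int(in_features)
        self.out_features = int(out_features)
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / self.in_features)
        self.W = rng.normal(0.0, std, size=(self.in_features,
                                            self.out_features)).astype(DTYPE)
        self.b = np.zeros(self.out_features, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def parameters(self):
        return (("W", self.W), ("b", self.b))

    def gradients(self):
        return (("W", self.dW), ("b", self.db))

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy, need_dx=True):
        self.dW = (self._x.T @ dy).astype(DTYPE)
        self.db = dy.sum(axis=0).astype(DTYPE)
        if not need_dx:
            return None
        return (dy @ self.W.T).astype(DTYPE)


class LeakyReLU(Layer):
    def __init__(self, alpha=0.3):
        self.alpha = float(alpha)

    def forward(self, x, train=False):
        if train:
            self._neg = x < 0
        # for alpha < 1 this is exactly x for x >= 0 and alpha*x otherwise
        return np.maximum(x, DTYPE(self.alpha) * x)

    def backward(self, dy, need_dx=True):
        return np.where(self._neg, DTYPE(self.alpha) * dy, dy)


class ConcatBranches(Layer):
    """Parallel branches on a shared input, concatenated channel-wise.

    The building block of inception-style modules: each branch is a list of
    layers applied in sequence to the same input; outputs are concatenated
    along the channel axis.
    """

    def __init__(self, branches):
        self.branches = [list(b) for b in branches]

    def parameters(self):
        for bi, branch in enumerate(self.branches):
            for li, layer in enumerate(branch):
                for name, arr in layer.parameters():
                    yield (f"b{bi}.l{li}.{name}", arr)

    def gradients(self):
        for bi, branch in enumerate(self.branches):
            for li, layer in enumerate(branch):
                for name, arr in layer.gradients():
                    yield (f"b{bi}.l{li}.{name}", arr)

    def forward(self, x, train=False):
        outs = []
        for branch in self.branches:
            h = x
            for layer in branch:
                h = layer.forward(h, train=train)
            outs.append(h)
        self._widths = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, dy, need_dx=True):
        dx = None
        start = 0
        for branch, w in zip(self.branches, self._widths):
            d = dy[:, start:start + w]
            start += w
            for li, layer in enumerate(reversed(branch)):
                last = li == len(branch) - 1
                d = layer.backward(d, need_dx=not (last and not need_dx))
            dx = d if dx is None else dx + d
        return dx
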