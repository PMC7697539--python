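"""Minimal layer library for 3D convolutional regression networks.

All layers operate on channel-first float32 arrays, keep their parameters in
``params`` (name -> array) and accumulate gradients in ``grads`` under the
same keys.  Kernel-size-1 convolutions are evaluated as batched matrix
products; larger kernels go through a per-sample im2col buffer so that each
sample costs one BLAS call per convolution instead of one per kernel offset.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv3d",
    "AxisNorm",
    "ReLU",
    "Dense",
    "GlobalAvgPool",
    "he_normal",
]


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He-normal initialization: N(0, sqrt(2/fan_in))."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Layer:
    """Base class: a differentiable module with named parameters."""

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    @property
    def n_non_trainable(self) -> int:
        return 0


def _same_padding(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """'same' padding: output = ceil(size / stride); asymmetric when odd."""
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    before = total // 2
    return out, before, total - before


class Conv3d(Layer):
    """3D convolution with 'same' padding and optional channel groups.

    weight: (cout, cin // groups, k, k, k); bias: (cout,).
    """

    def __init__(self, name, cin, cout, kernel, stride=1, groups=1, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__(name)
        if cin % groups or cout % groups:
            raise ValueError(
                f"{name}: groups={groups} must divide cin={cin} and cout={cout}")
        self.cin, self.cout, self.k, self.stride, self.groups = cin, cout, kernel, stride, groups
        rng = rng or np.random.default_rng(0)
        fan_in = (cin // groups) * kernel ** 3
        self.params["weight"] = he_normal(rng, (cout, cin // groups, kernel, kernel, kernel), fan_in)
        if bias:
            self.params["bias"] = np.zeros(cout, dtype=np.float32)
        self._cache = None

    # -- pointwise (k == 1, stride == 1) path --------------------------
    def _forward_pointwise(self, x, training):
        b, c = x.shape[:2]
        p = x.shape[2] * x.shape[3] * x.shape[4]
        g = self.groups
        x3 = np.ascontiguousarray(x).reshape(b, g, c // g, p)
        w = self.params["weight"].reshape(g, self.cout // g, c // g) \
            if g > 1 else self.params["weight"].reshape(1, self.cout, c)
        y = np.matmul(w, x3).reshape(b, self.cout, *x.shape[2:])
        if training:
            self._cache = ("pw", x3, x.shape)
        return y

    def _backward_pointwise(self, dy):
        _, x3, xshape = self._cache
        b = xshape[0]
        g = self.groups
        p = x3.shape[-1]
        dy3 = np.ascontiguousarray(dy).reshape(b, g, self.cout // g, p)
        w = self.params["weight"].reshape(g, self.cout // g, self.cin // g) \
            if g > 1 else self.params["weight"].reshape(1, self.cout, self.cin)
        # dW: sum over batch of dy @ x^T
        dw = np.matmul(dy3, x3.transpose(0, 1, 3, 2)).sum(axis=0)
        self.grads["weight"] = dw.reshape(self.params["weight"].shape)
        dx = np.matmul(w.transpose(0, 2, 1), dy3).reshape(xshape)
        self._cache = None
        return dx

    # -- stride-1 path: flattened-spatial im2col ------------------------
    # With the (padded) spatial axes flattened, the column of every kernel
    # offset is a contiguous shifted slice of the input buffer, so building
    # the GEMM operand costs one memcpy-speed copy.  The GEMM also produces
    # outputs at halo positions, which are cropped afterwards.
    def _flat_geom(self, shape):
        d, h, w = shape[2:]
        p = self.k // 2
        dp, hp, wp = d + 2 * p, h + 2 * p, w + 2 * p
        s = dp * hp * wp
        off_max = (self.k - 1) * (hp * wp + wp + 1)
        return (dp, hp, wp), s, s - off_max

    def _flat_cols(self, xflat, sout, hpwp, wp):
        from numpy.lib.stride_tricks import as_strided
        g, win, k = self.groups, self.cin // self.groups, self.k
        it = xflat.itemsize
        s = xflat.shape[-1]
        view = as_strided(
            xflat, shape=(g, win, k, k, k, sout),
            strides=(win * s * it, s * it, hpwp * it, wp * it, it, it))
        return np.ascontiguousarray(view).reshape(g, win * k ** 3, sout)

    def _forward_flat(self, x, training):
        b = x.shape[0]
        g, k = self.groups, self.k
        p = k // 2
        (dp, hp, wp), s, sout = self._flat_geom(x.shape)
        hpwp = hp * wp
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        xflat = xpad.reshape(b, self.cin, s)
        wmat = self.params["weight"].reshape(g, self.cout // g, (self.cin // g) * k ** 3)
        y = np.empty((b, self.cout) + x.shape[2:], dtype=np.float32)
        from numpy.lib.stride_tricks import as_strided
        for i in range(b):
            cols = self._flat_cols(xflat[i], sout, hpwp, wp)
            y_ext = np.matmul(wmat, cols)
            it = y_ext.itemsize
            yv = as_strided(
                y_ext, shape=(g, self.cout // g) + x.shape[2:],
                strides=(y_ext.strides[0], y_ext.strides[1], hpwp * it, wp * it, it))
            y[i] = yv.reshape((self.cout,) + x.shape[2:])
        if training:
            self._cache = ("flat", xflat, x.shape)
        return y

    def _backward_flat(self, dy):
        _, xflat, xshape = self._cache
        b = xshape[0]
        g, k = self.groups, self.k
        win = self.cin // g
        (dp, hp, wp), s, sout = self._flat_geom(xshape)
        hpwp = hp * wp
        wmat = self.params["weight"].reshape(g, self.cout // g, win * k ** 3)
        dw = np.zeros_like(wmat)
        dxflat = np.zeros_like(xflat)
        from numpy.lib.stride_tricks import as_strided
        offs = [dz * hpwp + dyy * wp + dx
                for dz in range(k) for dyy in range(k) for dx in range(k)]
        for i in range(b):
            # embed dy into the flattened halo layout (zeros elsewhere)
            dy_ext = np.zeros((g, self.cout // g, sout), dtype=np.float32)
            it = dy_ext.itemsize
            dv = as_strided(
                dy_ext, shape=(g, self.cout // g) + xshape[2:],
                strides=(dy_ext.strides[0], dy_ext.strides[1], hpwp * it, wp * it, it))
            dv[...] = dy[i].reshape((g, self.cout // g) + xshape[2:])
            cols = self._flat_cols(xflat[i], sout, hpwp, wp)
            dw += np.matmul(dy_ext, cols.transpose(0, 2, 1))
            dcols = np.matmul(wmat.transpose(0, 2, 1), dy_ext).reshape(
                g, win, k ** 3, sout)
            dxg = dxflat[i].reshape(g, win, s)
            for o, off in enumerate(offs):
                dxg[:, :, off:off + sout] += dcols[:, :, o, :]
        self.grads["weight"] = dw.reshape(self.params["weight"].shape)
        p = k // 2
        dxpad = dxflat.reshape(b, self.cin, dp, hp, wp)
        self._cache = None
        return np.ascontiguousarray(
            dxpad[:, :, p:dp - p, p:hp - p, p:wp - p])

    # -- general path: per-sample im2col -------------------------------
    def _geometry(self, shape):
        d, h, w = shape[2:]
        od, pd0, pd1 = _same_padding(d, self.k, self.stride)
        oh, ph0, ph1 = _same_padding(h, self.k, self.stride)
        ow, pw0, pw1 = _same_padding(w, self.k, self.stride)
        return (od, oh, ow), ((pd0, pd1), (ph0, ph1), (pw0, pw1))

    def _im2col(self, xpad_b, out):
        """xpad_b: (cin, D, H, W) one padded sample -> (g, win*k^3, P)."""
        od, oh, ow = out
        k, s, g = self.k, self.stride, self.groups
        win = self.cin // g
        cols = np.empty((g, win, k ** 3, od * oh * ow), dtype=np.float32)
        xg = xpad_b.reshape(g, win, *xpad_b.shape[1:])
        o = 0
        for dz in range(k):
            for dyy in range(k):
                for dx in range(k):
                    cols[:, :, o, :] = xg[
                        :, :,
                        dz:dz + od * s:s,
                        dyy:dyy + oh * s:s,
                        dx:dx + ow * s:s].reshape(g, win, -1)
                    o += 1
        return cols.reshape(g, win * k ** 3, od * oh * ow)

    def _forward_general(self, x, training):
        b = x.shape[0]
        out, pads = self._geometry(x.shape)
        od, oh, ow = out
        xpad = np.pad(x, ((0, 0), (0, 0), *pads))
        g = self.groups
        wmat = self.params["weight"].reshape(
            g, self.cout // g, (self.cin // g) * self.k ** 3)
        y = np.empty((b, self.cout, od, oh, ow), dtype=np.float32)
        for i in range(b):
            cols = self._im2col(xpad[i], out)
            y[i] = np.matmul(wmat, cols).reshape(self.cout, od, oh, ow)
        if training:
            self._cache = ("gen", xpad, x.shape, out, pads)
        return y

    def _backward_general(self, dy):
        _, xpad, xshape, out, pads = self._cache
        b = xshape[0]
        od, oh, ow = out
        g = self.groups
        k, s = self.k, self.stride
        win = self.cin // g
        wmat = self.params["weight"].reshape(g, self.cout // g, win * k ** 3)
        dw = np.zeros_like(wmat)
        dxpad = np.zeros_like(xpad)
        for i in range(b):
            cols = self._im2col(xpad[i], out)
            dyi = dy[i].reshape(g, self.cout // g, od * oh * ow)
            dw += np.matmul(dyi, cols.transpose(0, 2, 1))
            dcols = np.matmul(wmat.transpose(0, 2, 1), dyi).reshape(
                g, win, k ** 3, od * oh * ow)
            dxg = dxpad[i].reshape(g, win, *xpad.shape[2:])
            o = 0
            for dz in range(k):
                for dyy in range(k):
                    for dx in range(k):
                        dxg[:, :,
                            dz:dz + od * s:s,
                            dyy:dyy + oh * s:s,
                            dx:dx + ow * s:s] += dcols[:, :, o, :].reshape(
                                g, win, od, oh, ow)
                        o += 1
        self.grads["weight"] = dw.reshape(self.params["weight"].shape)
        (pd0, pd1), (ph0, ph1), (pw0, pw1) = pads
        self._cache = None
        return np.ascontiguousarray(
            dxpad[:, :,
                  pd0:dxpad.shape[2] - pd1,
                  ph0:dxpad.shape[3] - ph1,
                  pw0:dxpad.shape[4] - pw1])

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if self.k == 1 and self.stride == 1:
            y = self._forward_pointwise(x, training)
        elif self.stride == 1:
            y = self._forward_flat(x, training)
        else:
            y = self._forward_general(x, training)
        if "bias" in self.params:
            y += self.params["bias"][None, :, None, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if "bias" in self.params:
            self.grads["bias"] = dy.sum(axis=(0, 2, 3, 4))
        if self._cache[0] == "pw":
            return self._backward_pointwise(dy)
        if self._cache[0] == "flat":
            return self._backward_flat(dy)
        return self._backward_general(dy)


class AxisNorm(Layer):
    """Batch normalization over all axes except the trailing one.

    With channel-first 5D inputs this normalizes each position of the last
    spatial axis (size ``n``); with 2D inputs it is ordinary feature batch
    norm.  gamma/beta are trainable; moving mean/variance are not.
    """

    def __init__(self, name, n, momentum=0.99, eps=1e-3):
        super().__init__(name)
        self.n, self.momentum, self.eps = n, momentum, eps
        self.params["gamma"] = np.ones(n, dtype=np.float32)
        self.params["beta"] = np.zeros(n, dtype=np.float32)
        self.moving_mean = np.zeros(n, dtype=np.float32)
        self.moving_var = np.ones(n, dtype=np.float32)
        self._cache = None

    @property
    def n_params(self) -> int:
        return 4 * self.n

    @property
    def n_non_trainable(self) -> int:
        return 2 * self.n

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes, dtype=np.float32)
            var = x.var(axis=axes, dtype=np.float32)
            m = self.momentum
            self.moving_mean = (m * self.moving_mean + (1 - m) * mean).astype(np.float32)
            self.moving_var = (m * self.moving_var + (1 - m) * var).astype(np.float32)
        else:
            mean, var = self.moving_mean, self.moving_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * inv
        y = self.params["gamma"] * xhat + self.params["beta"]
        if training:
            self._cache = (xhat, inv, axes)
        return y.astype(np.float32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, axes = self._cache
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"]
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=axes)
              - xhat * (dxhat * xhat).mean(axis=axes)) * inv
        self._cache = None
        return dx.astype(np.float32, copy=False)


class ReLU(Layer):
    def __init__(self, name="relu"):
        super().__init__(name)
        self._mask = None

    def forward(self, x, training=False):
        y = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class GlobalAvgPool(Layer):
    """(b, c, d, h, w) -> (b, c), averaging over the spatial axes."""

    def __init__(self, name="gap"):
        super().__init__(name)
        self._shape = None

    def forward(self, x, training=False):
        if training:
            self._shape = x.shape
        return x.mean(axis=(2, 3, 4), dtype=np.float32)

    def backward(self, dy):
        b, c, d, h, w = self._shape
        return np.broadcast_to(
            dy[:, :, None, None, None] / (d * h * w), self._shape
        ).astype(np.float32)


class Dense(Layer):
    def __init__(self, name, din, dout, rng: np.random.Generator | None = None):
        super().__init__(name)
        rng = rng or np.random.default_rng(0)
        self.params["weight"] = he_normal(rng, (din, dout), din)
        self.params["bias"] = np.zeros(dout, dtype=np.float32)
        self._x = None

    def forward(self, x, training=False):
        if training:
            self._x = x
        return x @ self.params["weight"] + self.params["bias"]

    def backward(self, dy):
        self.grads["weight"] = self._x.T @ dy
        self.grads["bias"] = dy.sum(axis=0)
        dx = dy @ self.params["weight"].T
        self._x = None
        return dx
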