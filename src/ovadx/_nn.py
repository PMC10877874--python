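"""Minimal neural-network engine: numpy layers with manual backprop.

Implements exactly what the edge-output segmentation network needs —
im2col-based 2D convolution, transposed convolution (bilinear-initialized
learned upsampling), max-pooling, ReLU, residual blocks (basic and
bottleneck) and Adam. Single-threaded numpy makes runs bitwise
reproducible under a fixed seed; gradients are exact (verified by
finite differences in the test suite).

Layers expose ``params``/``grads`` dicts; ``forward`` caches what
``backward`` needs. Nothing here is specific to the tumor-segmentation
task; :mod:`ovadx.network` composes these pieces.
"""

from __future__ import annotations

import numpy as np

#: Default parameter dtype. float32 halves memory traffic, which dominates
#: im2col convolution cost on CPU; compute follows the parameter dtype, so
#: casting a network's parameters to float64 yields float64 compute (the
#: finite-difference gradient checks do exactly that).
DTYPE = np.float32

__all__ = [
    "DTYPE",
    "Conv2d",
    "ConvTranspose2d",
    "MaxPool2d",
    "ReLU",
    "BasicBlock",
    "BottleneckBlock",
    "Adam",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, k, k, ho, wo),
        strides=(s[0], s[1], s[2], s[3], stride * s[2], stride * s[3]),
    )
    return np.ascontiguousarray(view).reshape(n, c * k * k, ho * wo), (ho, wo)


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to image grid."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    cols = cols.reshape(n, c, k, k, ho, wo)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                cols[:, :, i, j]
            )
    return out[:, :, pad : hp - pad, pad : wp - pad] if pad else out


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def param_items(self):
        return [(name, self.params[name]) for name in sorted(self.params)]


class Conv2d(Layer):
    def __init__(self, c_in, c_out, k, stride=1, pad=None, rng=None):
        super().__init__()
        self.k, self.stride = k, stride
        self.pad = (k // 2) if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.params["W"] = (
            rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in)
        ).astype(DTYPE)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def forward(self, x):
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._x_shape = cols, x.shape
        w = self.params["W"]
        out = np.matmul(w.reshape(w.shape[0], -1)[None], cols)
        out += self.params["b"][:, None]
        return out.reshape(x.shape[0], w.shape[0], ho, wo)

    def backward(self, dout):
        n, c_out, ho, wo = dout.shape
        dflat = dout.reshape(n, c_out, ho * wo)
        w = self.params["W"]
        self.grads["W"] = (
            np.matmul(dflat, self._cols.transpose(0, 2, 1)).sum(axis=0)
        ).reshape(w.shape)
        self.grads["b"] = dflat.sum(axis=(0, 2))
        dcols = np.matmul(w.reshape(c_out, -1).T[None], dflat)
        return _col2im(dcols, self._x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Transposed convolution; with k=2f, stride=f, pad=f//2 it upsamples
    H×W to fH×fW. ``bilinear_init=True`` sets W to a per-channel bilinear
    interpolation kernel (c_in must equal c_out)."""

    def __init__(self, c_in, c_out, k, stride, pad, rng=None, bilinear_init=False):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad
        if bilinear_init:
            if c_in != c_out:
                raise ValueError("bilinear init needs c_in == c_out")
            factor = (k + 1) // 2
            center = factor - 1.0 if k % 2 == 1 else factor - 0.5
            og = np.ogrid[:k, :k]
            filt = (1 - abs(og[0] - center) / factor) * (
                1 - abs(og[1] - center) / factor
            )
            w = np.zeros((c_in, c_out, k, k))
            for i in range(c_in):
                w[i, i] = filt
            self.params["W"] = w.astype(DTYPE)
        else:
            rng = rng or np.random.default_rng(0)
            self.params["W"] = (
                rng.standard_normal((c_in, c_out, k, k))
                * np.sqrt(2.0 / (c_in * k * k))
            ).astype(DTYPE)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def out_size(self, h):
        return (h - 1) * self.stride + self.k - 2 * self.pad

    def forward(self, x):
        n, c_in, h, w = x.shape
        self._x = x
        wt = self.params["W"]
        c_out = wt.shape[1]
        ho, wo = self.out_size(h), self.out_size(w)
        cols = np.matmul(wt.reshape(c_in, -1).T[None], x.reshape(n, c_in, -1))
        out = _col2im(cols, (n, c_out, ho, wo), self.k, self.stride, self.pad)
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout):
        n, c_in, h, w = self._x.shape
        wt = self.params["W"]
        cols, _ = _im2col(dout, self.k, self.stride, self.pad)
        xin = self._x.reshape(n, c_in, -1)
        self.grads["W"] = (
            np.matmul(xin, cols.transpose(0, 2, 1)).sum(axis=0)
        ).reshape(wt.shape)
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        dx = np.matmul(wt.reshape(c_in, -1)[None], cols)
        return dx.reshape(self._x.shape)


class MaxPool2d(Layer):
    def __init__(self, k=3, stride=2, pad=1):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n * c, 1, h, w)
        cols, (ho, wo) = _im2col(xr, self.k, self.stride, self.pad)
        # padded zeros can win the max on negative inputs; pad with -inf instead
        if self.pad:
            mask = np.ones((n * c, 1, h, w), dtype=x.dtype)
            mcols, _ = _im2col(mask, self.k, self.stride, self.pad)
            cols = np.where(mcols > 0, cols, x.dtype.type(-np.inf))
        self._arg = cols.argmax(axis=1)
        self._x_shape, self._cols_shape = x.shape, cols.shape
        out = np.take_along_axis(cols, self._arg[:, None, :], axis=1)[:, 0]
        return out.reshape(n, c, ho, wo)

    def backward(self, dout):
        n, c, h, w = self._x_shape
        dcols = np.zeros(self._cols_shape, dtype=dout.dtype)
        dflat = dout.reshape(n * c, -1)
        np.put_along_axis(dcols, self._arg[:, None, :], dflat[:, None, :], axis=1)
        dx = _col2im(dcols, (n * c, 1, h, w), self.k, self.stride, self.pad)
        return dx.reshape(n, c, h, w)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class BasicBlock(Layer):
    """conv3x3 → relu → conv3x3, plus identity/1x1-projection skip, relu."""

    def __init__(self, c_in, c_out, stride=1, rng=None):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, 3, stride=stride, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, rng=rng)
        self.proj = (
            Conv2d(c_in, c_out, 1, stride=stride, pad=0, rng=rng)
            if (stride != 1 or c_in != c_out)
            else None
        )
        self.stride = stride
        self.c_out = c_out

    @property
    def sublayers(self):
        subs = [("conv1", self.conv1), ("conv2", self.conv2)]
        if self.proj is not None:
            subs.append(("proj", self.proj))
        return subs

    def forward(self, x):
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        s = self.proj.forward(x) if self.proj is not None else x
        out = y + s
        self._out_mask = out > 0
        return out * self._out_mask

    def backward(self, dout):
        dsum = dout * self._out_mask
        dx = self.conv1.backward(self.relu1.backward(self.conv2.backward(dsum)))
        if self.proj is not None:
            dx = dx + self.proj.backward(dsum)
        else:
            dx = dx + dsum
        return dx


class BottleneckBlock(Layer):
    """1x1 reduce → 3x3 (stride) → 1x1 expand, with projection skip."""

    def __init__(self, c_in, c_mid, c_out, stride=1, rng=None):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_mid, 1, pad=0, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_mid, c_mid, 3, stride=stride, rng=rng)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(c_mid, c_out, 1, pad=0, rng=rng)
        self.proj = (
            Conv2d(c_in, c_out, 1, stride=stride, pad=0, rng=rng)
            if (stride != 1 or c_in != c_out)
            else None
        )
        self.stride = stride
        self.c_out = c_out

    @property
    def sublayers(self):
        subs = [("conv1", self.conv1), ("conv2", self.conv2), ("conv3", self.conv3)]
        if self.proj is not None:
            subs.append(("proj", self.proj))
        return subs

    def forward(self, x):
        y = self.conv1.forward(x)
        y = self.relu1.forward(y)
        y = self.conv2.forward(y)
        y = self.relu2.forward(y)
        y = self.conv3.forward(y)
        s = self.proj.forward(x) if self.proj is not None else x
        out = y + s
        self._out_mask = out > 0
        return out * self._out_mask

    def backward(self, dout):
        dsum = dout * self._out_mask
        dy = self.conv3.backward(dsum)
        dy = self.relu2.backward(dy)
        dy = self.conv2.backward(dy)
        dy = self.relu1.backward(dy)
        dx = self.conv1.backward(dy)
        if self.proj is not None:
            dx = dx + self.proj.backward(dsum)
        else:
            dx = dx + dsum
        return dx


class Adam:
    """Adam over a fixed list of (layer, param-name) slots."""

    def __init__(self, slots, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.slots = list(slots)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.slots]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.slots]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (layer, name) in enumerate(self.slots):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
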