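"""Minimal convolutional-network framework on NumPy.

Provides exactly the layers the attenuation-map generator needs — 2-D
convolution (stride 1 and 2), transposed convolution, batch normalization,
ReLU, dropout — with hand-written backward passes, plus an Adam optimizer.
Convolutions are computed as im2col matrix products; the transposed
convolution and all input gradients go through the exact adjoint
(``col2im``), so every layer's gradient can be verified against finite
differences.

Tensors are ``(N, C, H, W)`` float64 arrays.  All randomness (weight
initialisation, dropout masks) is drawn from explicitly passed
``numpy.random.Generator`` objects.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: dtype of network parameters and activations; float32 keeps CPU training
#: fast, float64 is used in the gradient-check tests
DEFAULT_DTYPE = np.float32


def _conv_geometry(h, w, k, stride, pad):
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    return ho, wo


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, L) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # (N, C, ho, wo, k, k) -> (N, C, k, k, ho, wo)
    win = win.transpose(0, 1, 4, 5, 2, 3)
    ho, wo = win.shape[4], win.shape[5]
    return np.ascontiguousarray(win).reshape(n, c * k * k, ho * wo)


def col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Exact adjoint of :func:`im2col`: scatter-add patches back.

    Each of the k*k kernel offsets maps to a disjoint strided slice of the
    padded image, so the scatter is k*k vectorised strided additions.
    """
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho, wo = _conv_geometry(h, w, k, stride, pad)
    blocks = cols.reshape(n, c, k, k, ho, wo)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for a in range(k):
        for b in range(k):
            out[:, :, a : a + stride * ho : stride, b : b + stride * wo : stride] += blocks[
                :, :, a, b
            ]
    return out[:, :, pad : pad + h, pad : pad + w] if pad else out


class Layer:
    """Base class; subclasses implement forward/backward and expose params."""

    def params(self):  # list of (name, value, grad) triples by reference
        return []

    def forward(self, x, training, rng=None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, He-initialised, optional stride-2 downsampling."""

    def __init__(self, cin, cout, k=3, stride=1, pad=1, rng=None, dtype=None):
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        dtype = dtype or DEFAULT_DTYPE
        scale = np.sqrt(2.0 / (cin * k * k))
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, scale, size=(cout, cin * k * k)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("w", self), ("b", self)]

    def forward(self, x, training=False, rng=None):
        self._x_shape = x.shape
        self._cols = im2col(x, self.k, self.stride, self.pad)
        n = x.shape[0]
        ho, wo = _conv_geometry(x.shape[2], x.shape[3], self.k, self.stride, self.pad)
        out = np.matmul(self.w, self._cols)  # (O, CK) @ (N, CK, L) -> (N, O, L)
        out += self.b[None, :, None]
        return out.reshape(n, self.cout, ho, wo)

    def backward(self, dy):
        n = dy.shape[0]
        dyf = dy.reshape(n, self.cout, -1)
        self.dw += np.einsum("nol,ncl->oc", dyf, self._cols, optimize=True)
        self.db += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.w.T, dyf)
        return col2im(dcols, self._x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Stride-s transposed convolution (adjoint of a stride-s convolution)."""

    def __init__(self, cin, cout, k=2, stride=2, rng=None, dtype=None):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        dtype = dtype or DEFAULT_DTYPE
        scale = np.sqrt(2.0 / (cin * k * k))
        rng = rng or np.random.default_rng(0)
        # stored as the (cin, cout*k*k) matrix of the underlying conv adjoint
        self.w = rng.normal(0.0, scale, size=(cin, cout * k * k)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("w", self), ("b", self)]

    def forward(self, x, training=False, rng=None):
        n, c, h, w = x.shape
        self._x = x
        ho, wo = h * self.stride, w * self.stride
        self._out_shape = (n, self.cout, ho, wo)
        xf = x.reshape(n, c, h * w)
        cols = np.matmul(self.w.T, xf)  # (cout*k*k, cin) @ (N, cin, L)
        out = col2im(cols, self._out_shape, self.k, self.stride, 0)
        # col2im over an output grid of (ho_conv, wo_conv)=(h, w) positions
        return out + self.b[None, :, None, None]

    def backward(self, dy):
        n = dy.shape[0]
        cols = im2col(dy, self.k, self.stride, 0)  # (N, cout*k*k, h*w)
        xf = self._x.reshape(n, self.cin, -1)
        self.dw += np.einsum("ncl,nml->cm", xf, cols, optimize=True)
        self.db += dy.sum(axis=(0, 2, 3))
        dx = np.matmul(self.w, cols)
        return dx.reshape(self._x.shape)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=None):
        dtype = dtype or DEFAULT_DTYPE
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros(channels, dtype=dtype)
        self.dbeta = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [("gamma", self), ("beta", self)]

    def forward(self, x, training=False, rng=None):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) / self._std
        self._training = training
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        self.dgamma += (dy * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta += dy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        if not self._training:
            return dy * g / self._std
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        return (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / self._std


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity when rate is 0 or in evaluation mode."""

    def __init__(self, rate):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        u = rng.random(x.shape, dtype=np.float32)
        self._mask = ((u < keep) / np.float32(keep)).astype(x.dtype, copy=False)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, training=False, rng=None):
        for l in self.layers:
            x = l.forward(x, training=training, rng=rng)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


_PARAM_GRAD = {"w": "dw", "b": "db", "gamma": "dgamma", "beta": "dbeta"}


def iter_params(layer: Layer):
    """Yield (owner, attr_name, grad_name) for every trainable tensor."""
    for name, owner in layer.params():
        yield owner, name, _PARAM_GRAD[name]


def zero_grads(layer: Layer) -> None:
    for owner, name, gname in iter_params(layer):
        getattr(owner, gname)[...] = 0.0


def get_state(layer: Layer) -> list[np.ndarray]:
    """Deep copies of all trainable tensors (plus BN running stats)."""
    state = [getattr(o, n).copy() for o, n, _ in iter_params(layer)]
    for o, n, _ in iter_params(layer):
        if isinstance(o, BatchNorm2d) and n == "gamma":
            state.append(o.running_mean.copy())
            state.append(o.running_var.copy())
    return state


def set_state(layer: Layer, state: list[np.ndarray]) -> None:
    i = 0
    for o, n, _ in iter_params(layer):
        getattr(o, n)[...] = state[i]
        i += 1
    for o, n, _ in iter_params(layer):
        if isinstance(o, BatchNorm2d) and n == "gamma":
            o.running_mean[...] = state[i]
            o.running_var[...] = state[i + 1]
            i += 2


class Adam:
    """Adam optimizer over a layer's parameters."""

    def __init__(self, layer: Layer, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layer = layer
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(o, n)) for o, n, _ in iter_params(layer)]
        self.v = [np.zeros_like(getattr(o, n)) for o, n, _ in iter_params(layer)]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, (o, n, gname) in enumerate(iter_params(self.layer)):
            g = getattr(o, gname)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            getattr(o, n)[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    """Plain SGD with optional momentum (alternative optimizer)."""

    def __init__(self, layer: Layer, lr=1e-3, momentum=0.9):
        self.layer = layer
        self.lr, self.momentum = lr, momentum
        self.v = [np.zeros_like(getattr(o, n)) for o, n, _ in iter_params(layer)]

    def step(self) -> None:
        for i, (o, n, gname) in enumerate(iter_params(self.layer)):
            g = getattr(o, gname)
            self.v[i] = self.momentum * self.v[i] - self.lr * g
            getattr(o, n)[...] += self.v[i]
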