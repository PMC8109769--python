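"""Neural-network layers with explicit forward/backward passes.

Each layer stores its parameters in ``self.params`` and, after ``backward``,
the matching gradients in ``self.grads`` (same keys, same shapes; ``backward``
overwrites rather than accumulates).  Batches are NCHW for spatial layers.
"""

from __future__ import annotations

import numpy as np

from .ops import (
    col2im,
    conv_out_size,
    gather_patches,
    im2col,
    pad_hw,
    scatter_patches,
    truncated_normal,
)

def he_sd(fan_in: int) -> float:
    """Scale for ReLU-family activations; keeps activation magnitude O(1)
    through deep stacks without normalization layers."""
    return float(np.sqrt(2.0 / fan_in))


class Layer:
    """Base class: a differentiable op, possibly with parameters."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.params["w"] = truncated_normal((n_in, n_out), he_sd(n_in), rng, dtype)
        self.params["b"] = np.zeros(n_out, dtype=dtype)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"].T


class Conv2d(Layer):
    """k*k convolution, stride ``stride``, symmetric zero padding ``pad``."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.params["w"] = truncated_normal((c_out, c_in * k * k), he_sd(c_in * k * k), rng, dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)

    def forward(self, x, train=False):
        self._x_shape = x.shape
        cols, (ho, wo) = im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        out = np.matmul(self.params["w"], cols)  # (N, c_out, Ho*Wo)
        out += self.params["b"][:, None]
        return out.reshape(x.shape[0], self.c_out, ho, wo)

    def backward(self, dout, compute_dx: bool = True):
        n = dout.shape[0]
        dflat = dout.reshape(n, self.c_out, -1)
        self.grads["w"] = np.einsum("nol,nkl->ok", dflat, self._cols, optimize=True)
        self.grads["b"] = dflat.sum(axis=(0, 2))
        if not compute_dx:
            return None
        dcols = np.matmul(self.params["w"].T, dflat)
        return col2im(dcols, self._x_shape, self.k, self.stride, self.pad)

    def out_size(self, size: int) -> int:
        return conv_out_size(size, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Fractionally-strided convolution (the adjoint of a strided Conv2d).

    With k=5, stride=2, pad=2, output_padding=1 the spatial side exactly
    doubles — the upsampling stage of a DCGAN-style generator.  For that
    geometry the op is evaluated by sub-pixel (parity) decomposition: each
    of the four output-pixel parities is a small stride-1 convolution over
    the input, so the whole layer reduces to dense matrix products instead
    of strided scatter-adds.  Other geometries fall back to the generic
    scatter formulation.
    """

    # (input-tap offsets u into a 3x3 stride-1 patch, kernel indices t) per parity
    _PARITY_TAPS = {0: ((0, 1, 2), (4, 2, 0)), 1: ((1, 2), (3, 1))}

    def __init__(self, c_in: int, c_out: int, k: int = 5, stride: int = 2,
                 pad: int = 2, output_padding: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.k, self.stride, self.pad, self.outpad = k, stride, pad, output_padding
        self.c_in, self.c_out = c_in, c_out
        # fan-in per output pixel of the fractionally-strided conv
        self.params["w"] = truncated_normal(
            (c_in, c_out * k * k), he_sd(max(1, c_in * k * k // (stride * stride))), rng, dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self._subpixel = (k, stride, pad, output_padding) == (5, 2, 2, 1)

    def out_size(self, size: int) -> int:
        return (size - 1) * self.stride - 2 * self.pad + self.k + self.outpad

    def forward(self, x, train=False):
        if self._subpixel:
            return self._forward_subpixel(x)
        n, c, h, w = x.shape
        self._x_flat = x.reshape(n, c, h * w)
        self._hw_in = (h, w)
        cols = np.einsum("ck,ncl->nkl", self.params["w"], self._x_flat, optimize=True)
        canvas = scatter_patches(cols, h, w, self.k, self.stride)
        out_h, out_w = self.out_size(h), self.out_size(w)
        out = canvas[:, :, self.pad : self.pad + out_h, self.pad : self.pad + out_w]
        out = out + self.params["b"][:, None, None]
        return out

    def backward(self, dout):
        if self._subpixel:
            return self._backward_subpixel(dout)
        n = dout.shape[0]
        h, w = self._hw_in
        ch = (h - 1) * self.stride + self.k
        cw = (w - 1) * self.stride + self.k
        dcanvas = np.zeros((n, self.c_out, ch, cw), dtype=dout.dtype)
        dcanvas[:, :, self.pad : self.pad + dout.shape[2], self.pad : self.pad + dout.shape[3]] = dout
        dcols = gather_patches(dcanvas, h, w, self.k, self.stride)
        self.grads["w"] = np.einsum("ncl,nkl->ck", self._x_flat, dcols, optimize=True)
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        dx = np.einsum("ck,nkl->ncl", self.params["w"], dcols, optimize=True)
        return dx.reshape(n, self.c_in, h, w)

    # -- sub-pixel path -----------------------------------------------------
    # out[2a+py, 2b+px] = sum_{u,v} W[t_y(py,u), t_x(px,v)] * x[a-1+u, b-1+v]
    # The four parities are evaluated in ONE matrix product against a
    # (4*c_out, c_in*9) weight matrix whose invalid-tap entries are zero, so
    # the data path is a single stride-1 im2col plus one GEMM.

    def _parity_big_weight(self) -> np.ndarray:
        w4 = self.params["w"].reshape(self.c_in, self.c_out, self.k, self.k)
        big = np.zeros((4 * self.c_out, self.c_in * 9), dtype=w4.dtype)
        for p, (py, px) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            uy, ty = self._PARITY_TAPS[py]
            ux, tx = self._PARITY_TAPS[px]
            blk = big[p * self.c_out : (p + 1) * self.c_out].reshape(self.c_out, self.c_in, 3, 3)
            for i, (u, t_y) in enumerate(zip(uy, ty)):
                for j, (v, t_x) in enumerate(zip(ux, tx)):
                    blk[:, :, u, v] = w4[:, :, t_y, t_x].T
        return big

    def _forward_subpixel(self, x):
        n, c, h, w = x.shape
        self._hw_in = (h, w)
        cols, _ = im2col(x, 3, 1, 1)
        self._cols = cols
        out_all = np.matmul(self._parity_big_weight(), cols)  # (n, 4*c_out, h*w)
        out = np.empty((n, self.c_out, 2 * h, 2 * w), dtype=x.dtype)
        for p, (py, px) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            out[:, :, py::2, px::2] = out_all[:, p * self.c_out : (p + 1) * self.c_out].reshape(
                n, self.c_out, h, w)
        out += self.params["b"][:, None, None]
        return out

    def _backward_subpixel(self, dout):
        n = dout.shape[0]
        h, w = self._hw_in
        c = self.c_in
        dall = np.empty((n, 4 * self.c_out, h * w), dtype=dout.dtype)
        for p, (py, px) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            dall[:, p * self.c_out : (p + 1) * self.c_out] = np.ascontiguousarray(
                dout[:, :, py::2, px::2]).reshape(n, self.c_out, h * w)
        dbig = np.tensordot(dall, self._cols, axes=([0, 2], [0, 2]))  # (4*c_out, c*9)
        dw4 = np.zeros((self.c_in, self.c_out, self.k, self.k), dtype=dout.dtype)
        for p, (py, px) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            uy, ty = self._PARITY_TAPS[py]
            ux, tx = self._PARITY_TAPS[px]
            blk = dbig[p * self.c_out : (p + 1) * self.c_out].reshape(self.c_out, c, 3, 3)
            for u, t_y in zip(uy, ty):
                for v, t_x in zip(ux, tx):
                    dw4[:, :, t_y, t_x] += blk[:, :, u, v].T
        self.grads["w"] = dw4.reshape(self.c_in, self.c_out * self.k * self.k)
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        dcols = np.matmul(self._parity_big_weight().T, dall)
        return col2im(dcols, (n, c, h, w), 3, 1, 1)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class Tanh(Layer):
    def forward(self, x, train=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y * self._y)


class Dropout(Layer):
    """Inverted dropout; identity when ``train`` is False or rate is 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (u < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        super().__init__()
        self.shape = shape

    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C) mean over the spatial grid."""

    def forward(self, x, train=False):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        h, w = self._hw
        return np.broadcast_to(dout[:, :, None, None], dout.shape + (h, w)).copy() / (h * w)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout, need_input_grad: bool = True):
        first = self.layers[0]
        for layer in reversed(self.layers):
            if layer is first and not need_input_grad and isinstance(layer, Conv2d):
                return layer.backward(dout, compute_dx=False)
            dout = layer.backward(dout)
        return dout

    def param_layers(self) -> list[Layer]:
        return [l for l in self.layers if l.params]

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)
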