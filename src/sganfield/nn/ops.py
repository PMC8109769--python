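"""Low-level array ops for convolutional layers.

Everything works on NCHW batches.  Convolutions are expressed as matrix
products against unrolled patches (im2col); their adjoints scatter patch
columns back onto the image plane (col2im).  The scatter loops run over the
k*k kernel offsets only, so each iteration is a vectorized strided-slice add.
"""

from __future__ import annotations

import numpy as np


def pad_hw(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def conv_out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Unroll k*k patches of ``x`` (N,C,H,W) into columns (N, C*k*k, Ho*Wo)."""
    xp = pad_hw(x, pad)
    n, c, hp, wp = xp.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    s0, s1, s2, s3 = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, k, k, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return win.reshape(n, c * k * k, ho * wo), (ho, wo)


def col2im(cols: np.ndarray, x_shape: tuple[int, ...], k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add columns back to (N,C,H,W)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    cols6 = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols6[:, :, i, j]
    if pad == 0:
        return xp
    return xp[:, :, pad : pad + h, pad : pad + w]


def scatter_patches(cols: np.ndarray, h: int, w: int, k: int, stride: int) -> np.ndarray:
    """Scatter one k*k patch per input pixel onto a canvas (transposed conv).

    ``cols`` has shape (N, C*k*k, H*W); pixel (i,j) writes its patch with
    top-left corner at (i*stride, j*stride).  Returns the full canvas of side
    (H-1)*stride + k; the caller crops to the requested output size.
    """
    n = cols.shape[0]
    c = cols.shape[1] // (k * k)
    cols6 = cols.reshape(n, c, k, k, h, w)
    ch = (h - 1) * stride + k
    cw = (w - 1) * stride + k
    canvas = np.zeros((n, c, ch, cw), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            canvas[:, :, i : i + stride * h : stride, j : j + stride * w : stride] += cols6[:, :, i, j]
    return canvas


def gather_patches(canvas: np.ndarray, h: int, w: int, k: int, stride: int) -> np.ndarray:
    """Adjoint of :func:`scatter_patches`; returns (N, C*k*k, H*W)."""
    n, c = canvas.shape[:2]
    cols6 = np.empty((n, c, k, k, h, w), dtype=canvas.dtype)
    for i in range(k):
        for j in range(k):
            cols6[:, :, i, j] = canvas[:, :, i : i + stride * h : stride, j : j + stride * w : stride]
    return cols6.reshape(n, c * k * k, h * w)


def truncated_normal(shape, sd: float, rng: np.random.Generator, dtype=np.float32) -> np.ndarray:
    """Normal(0, sd) resampled until every draw lies within two sd."""
    out = rng.normal(0.0, sd, size=shape)
    bad = np.abs(out) > 2.0 * sd
    while bad.any():
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) > 2.0 * sd
    return out.astype(dtype)
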