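"""Forward/backward kernels for the segmentation network.

Everything is NHWC float32 and implemented with im2col + BLAS matmuls, which
is the fastest portable route for small CPU models. Each layer caches what its
backward pass needs; ``backward`` must be called right after the matching
``forward``.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, 9C) patches of the 3x3 neighborhood, zero-padded."""
    N, H, W, C = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((N, H, W, 9 * C), dtype=x.dtype)
    k = 0
    for i in range(3):
        for j in range(3):
            cols[..., k * C:(k + 1) * C] = xp[:, i:i + H, j:j + W, :]
            k += 1
    return cols.reshape(-1, 9 * C)


def _col2im3(dcols: np.ndarray, shape) -> np.ndarray:
    """Adjoint of :func:`_im2col3`."""
    N, H, W, C = shape
    dcols = dcols.reshape(N, H, W, 9 * C)
    dxp = np.zeros((N, H + 2, W + 2, C), dtype=dcols.dtype)
    k = 0
    for i in range(3):
        for j in range(3):
            dxp[:, i:i + H, j:j + W, :] += dcols[..., k * C:(k + 1) * C]
            k += 1
    return dxp[:, 1:-1, 1:-1, :]


class Conv:
    """k×k convolution (k in {1, 3}), stride 1, same padding, optional ReLU."""

    def __init__(self, k: int, cin: int, cout: int, rng: np.random.Generator,
                 relu: bool = True):
        if k not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are used here")
        self.k, self.cin, self.cout, self.relu = k, cin, cout, relu
        fan_in = k * k * cin
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, cout)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        N, H, W, _ = x.shape
        self._cols = _im2col3(x) if self.k == 3 else x.reshape(-1, self.cin)
        z = self._cols @ self.W + self.b
        if self.relu:
            self._mask = z > 0
            z = z * self._mask
        return z.reshape(N, H, W, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy.reshape(-1, self.cout).astype(F32)
        if self.relu:
            dy = dy * self._mask
        self.dW = self._cols.T @ dy
        self.db = dy.sum(axis=0)
        dcols = dy @ self.W.T
        if self.k == 3:
            return _col2im3(dcols, self._xshape)
        return dcols.reshape(self._xshape)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class MaxPool2:
    """2x2 max pooling, stride 2. Ties route the gradient to the first maximum."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, H, W, C = x.shape
        xr = x.reshape(N, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
        flat = xr.reshape(N, H // 2, W // 2, C, 4)
        self._arg = flat.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, H, W, C = self._xshape
        dflat = np.zeros((N, H // 2, W // 2, C, 4), dtype=F32)
        np.put_along_axis(dflat, self._arg[..., None], dy[..., None].astype(F32), axis=-1)
        dxr = dflat.reshape(N, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dxr.reshape(N, H, W, C)


class Upsample2:
    """Nearest-neighbor 2x up-sampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, H, W, C = self._xshape
        return dy.reshape(N, H, 2, W, 2, C).sum(axis=(2, 4)).astype(F32)
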