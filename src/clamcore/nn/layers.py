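"""Minimal 3D convolutional network layers with explicit backpropagation.

All layers operate on arrays of shape ``(N, C, X, Y, Z)``. Each layer caches
what its backward pass needs during ``forward`` and exposes parameter and
gradient dictionaries for the optimizer. Convolutions are valid (no padding)
cross-correlations evaluated via strided sliding-window views and einsum,
which keeps the arithmetic in BLAS and the implementation free of Python
loops over voxels.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: stateless unless it declares params/grads."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3D(Layer):
    """Valid 3D cross-correlation, He-initialized.

    Forward and both backward products are evaluated as a single GEMM on an
    im2col matrix; the input gradient is reassembled by a col2im
    scatter-add over the kernel offsets.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int, int],
        rng: np.random.Generator,
        stride: tuple[int, int, int] = (1, 1, 1),
    ) -> None:
        super().__init__()
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        fan_in = in_channels * int(np.prod(kernel))
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, *kernel)
        ).astype(np.float32)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # (N, C, ox, oy, oz, kx, ky, kz) -> (N*ox*oy*oz, C*kx*ky*kz)
        sx, sy, sz = self.stride
        win = sliding_window_view(x, self.kernel, axis=(2, 3, 4))[
            :, :, ::sx, ::sy, ::sz
        ]
        n, c, ox, oy, oz = win.shape[:5]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        self._out_spatial = (ox, oy, oz)
        return cols.reshape(n * ox * oy * oz, c * int(np.prod(self.kernel)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        cols = self._im2col(x)
        self._cols = cols
        w = self.params["W"]
        f = w.shape[0]
        y = cols @ w.reshape(f, -1).T + self.params["b"]
        n = x.shape[0]
        ox, oy, oz = self._out_spatial
        return np.ascontiguousarray(
            y.reshape(n, ox, oy, oz, f).transpose(0, 4, 1, 2, 3)
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w = self.params["W"]
        f, c = w.shape[0], w.shape[1]
        kx, ky, kz = self.kernel
        n, _, ox, oy, oz = dy.shape
        dy_mat = np.ascontiguousarray(
            dy.transpose(0, 2, 3, 4, 1)
        ).reshape(-1, f)
        self.grads["W"] = (dy_mat.T @ self._cols).reshape(w.shape)
        self.grads["b"] = dy_mat.sum(axis=0)
        dcols = (dy_mat @ w.reshape(f, -1)).reshape(
            n, ox, oy, oz, c, kx, ky, kz
        )
        dx = np.zeros(self._x_shape, dtype=dy.dtype)
        sx, sy, sz = self.stride
        for i in range(kx):
            for j in range(ky):
                for k in range(kz):
                    dx[
                        :,
                        :,
                        i : i + sx * (ox - 1) + 1 : sx,
                        j : j + sy * (oy - 1) + 1 : sy,
                        k : k + sz * (oz - 1) + 1 : sz,
                    ] += dcols[:, :, :, :, :, i, j, k].transpose(0, 4, 1, 2, 3)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool3D(Layer):
    """Non-overlapping max pooling; trailing remainders are dropped.

    Gradient is split equally among tied maxima within a pool cell.
    """

    def __init__(self, pool: tuple[int, int, int]) -> None:
        super().__init__()
        self.pool = tuple(pool)

    def _blocks(self, x: np.ndarray) -> np.ndarray:
        px, py, pz = self.pool
        n, c, X, Y, Z = x.shape
        ox, oy, oz = X // px, Y // py, Z // pz
        if min(ox, oy, oz) < 1:
            raise ValueError(
                f"pool {self.pool} larger than feature map {(X, Y, Z)}"
            )
        crop = x[:, :, : ox * px, : oy * py, : oz * pz]
        return crop.reshape(n, c, ox, px, oy, py, oz, pz)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        blocks = self._blocks(x)
        self._blocks_cache = blocks
        y = blocks.max(axis=(3, 5, 7))
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        blocks = self._blocks_cache
        y = self._y[:, :, :, None, :, None, :, None]
        mask = blocks == y
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        dblocks = mask * (dy[:, :, :, None, :, None, :, None] / counts)
        n, c, ox, px, oy, py, oz, pz = dblocks.shape
        dx = np.zeros(self._x_shape, dtype=dy.dtype)
        dx[:, :, : ox * px, : oy * py, : oz * pz] = dblocks.reshape(
            n, c, ox * px, oy * py, oz * pz
        )
        return dx


class GlobalAvgPool(Layer):
    """(N, C, X, Y, Z) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, X, Y, Z = self._shape
        scale = 1.0 / (X * Y * Z)
        return np.broadcast_to(
            dy[:, :, None, None, None] * scale, self._shape
        ).copy()


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)
        ).astype(np.float32)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n
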