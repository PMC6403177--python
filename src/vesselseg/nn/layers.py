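"""Minimal NumPy layers with explicit forward/backward passes.

Tensors are ``(N, C, H, W)`` float32 arrays.  Each layer caches what its
backward pass needs during ``forward`` and exposes its trainable arrays
through ``params`` / ``grads`` dictionaries so an optimizer can update
them in place.  Convolutions use im2col so the heavy lifting is a single
matrix product per batch.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "Dropout", "MaxPool2x2", "Upsample2x", "glorot_uniform_limit"]


def glorot_uniform_limit(fan_in: int, fan_out: int) -> float:
    """Half-width L of the Glorot/Xavier uniform range [-L, L],
    L = sqrt(6 / (fan_in + fan_out))."""
    return float(np.sqrt(6.0 / (fan_in + fan_out)))


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) for stride-1 same-padded k x k conv."""
    N, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((N, C, k * k, H, W), dtype=x.dtype)
    for dy in range(k):
        for dx in range(k):
            cols[:, :, dy * k + dx] = x[:, :, dy : dy + H, dx : dx + W]
    return cols.reshape(N, C * k * k, H * W)


def _col2im(dcols: np.ndarray, shape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add of column gradients)."""
    N, C, H, W = shape
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(N, C, k * k, H, W)
    for dy in range(k):
        for dx in range(k):
            dxp[:, :, dy : dy + H, dx : dx + W] += dcols[:, :, dy * k + dx]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d:
    """k x k convolution, stride 1, same padding, with bias.

    Weights are Glorot-uniform initialized with the Keras convention for
    convolutional fans: fan_in = C_in*k*k, fan_out = C_out*k*k.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        limit = glorot_uniform_limit(c_in * k * k, c_out * k * k)
        w = rng.uniform(-limit, limit, size=(c_out, c_in, k, k)).astype(np.float32)
        self.params = {"w": w, "b": np.zeros(c_out, dtype=np.float32)}
        self.grads = {"w": np.zeros_like(w), "b": np.zeros_like(self.params["b"])}
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    @property
    def n_params(self) -> int:
        return self.params["w"].size + self.params["b"].size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, C, H, W = x.shape
        self._xshape = x.shape
        cols = _im2col(x, self.k, self.pad)
        self._cols = cols if train else None
        w2 = self.params["w"].reshape(self.c_out, -1)
        out = np.matmul(w2, cols)  # (N, c_out, H*W)
        out += self.params["b"][None, :, None]
        return out.reshape(N, self.c_out, H, W)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, _, H, W = dout.shape
        dout2 = dout.reshape(N, self.c_out, H * W)
        assert self._cols is not None, "backward requires forward(train=True)"
        self.grads["w"][...] = (
            np.matmul(dout2, self._cols.transpose(0, 2, 1)).sum(axis=0)
        ).reshape(self.params["w"].shape)
        self.grads["b"][...] = dout2.sum(axis=(0, 2))
        w2 = self.params["w"].reshape(self.c_out, -1)
        dcols = np.matmul(w2.T, dout2)
        dx = _col2im(dcols, self._xshape, self.k, self.pad)
        self._cols = None
        return dx


class ReLU:
    params: dict = {}
    grads: dict = {}
    n_params = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0 if train else None
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout:
    """Inverted dropout; identity when evaluating or when rate == 0."""

    params: dict = {}
    grads: dict = {}
    n_params = 0

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class MaxPool2x2:
    """2 x 2 max pooling with stride 2 (spatial dims must be even)."""

    params: dict = {}
    grads: dict = {}
    n_params = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {(H, W)}")
        windows = (
            x.reshape(N, C, H // 2, 2, W // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H // 2, W // 2, 4)
        )
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._inshape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, Ho, Wo = dout.shape
        dwin = np.zeros((N, C, Ho, Wo, 4), dtype=dout.dtype)
        np.put_along_axis(dwin, self._idx[..., None], dout[..., None], axis=-1)
        H, W = self._inshape[2], self._inshape[3]
        return (
            dwin.reshape(N, C, Ho, Wo, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H, W)
        )


class Upsample2x:
    """Parameter-free 2x nearest-neighbor up-sampling."""

    params: dict = {}
    grads: dict = {}
    n_params = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H, W = dout.shape
        return dout.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))
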