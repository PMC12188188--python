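"""Minimal 1-D neural-network layers with explicit forward/backward passes.

All layers operate on arrays of shape ``(n, channels, length)`` (channel-major,
which keeps the convolution inner loop a single GEMM).  Each layer caches what
its backward pass needs during ``forward``; ``backward`` consumes the cache and
accumulates parameter gradients into ``grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: parameter container + forward/backward contract."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.trainable = True

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def n_parameters(self) -> int:
        if not self.trainable:
            return 0
        return int(sum(p.size for p in self.params.values()))


class Conv1d(Layer):
    """Same-length 1-D convolution (odd kernel, zero padding)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator | None = None,
                 dtype: np.dtype = np.float32) -> None:
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.pad = (kernel_size - 1) // 2
        rng = rng or np.random.default_rng(0)
        # He initialisation for ReLU nets
        scale = np.sqrt(2.0 / (in_channels * kernel_size))
        self.params["W"] = (rng.standard_normal(
            (out_channels, in_channels, kernel_size)) * scale).astype(dtype)
        self.params["b"] = np.zeros(out_channels, dtype=dtype)
        self._cols: np.ndarray | None = None
        self._in_len = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, L = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {c}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        # (n, c, L, k) -> (n*L, c*k)
        win = sliding_window_view(xp, self.kernel_size, axis=2)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            n * L, c * self.kernel_size)
        Wm = self.params["W"].reshape(self.out_channels, -1)
        y = cols @ Wm.T + self.params["b"]
        self._cols, self._in_len = cols, L
        return np.ascontiguousarray(
            y.reshape(n, L, self.out_channels).transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, o, L = dy.shape
        k, ci = self.kernel_size, self.in_channels
        dyr = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(n * L, o)
        self.grads["W"] = (dyr.T @ self._cols).reshape(self.params["W"].shape)
        self.grads["b"] = dyr.sum(axis=0)
        dcols = (dyr @ self.params["W"].reshape(o, -1)).reshape(n, L, ci, k)
        dxp = np.zeros((n, ci, L + 2 * self.pad), dtype=dy.dtype)
        for j in range(k):
            dxp[:, :, j:j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
        self._cols = None
        return dxp[:, :, self.pad:self.pad + L]


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over (batch, position)."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype: np.dtype = np.float32) -> None:
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        # running statistics are state, not trainable parameters
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        g = self.params["gamma"][:, None]
        b = self.params["beta"][:, None]
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * ivar[:, None]
        self._cache = ("train" if train else "eval", xhat,
                       ivar.astype(x.dtype))
        return g * xhat + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mode, xhat, ivar = self._cache
        g = self.params["gamma"][:, None]
        if mode == "eval":
            # eval-mode backward (used by Grad-CAM): stats are constants
            self.grads.setdefault("gamma", np.zeros_like(self.params["gamma"]))
            self.grads.setdefault("beta", np.zeros_like(self.params["beta"]))
            return dy * g * ivar[:, None]
        m = dy.shape[0] * dy.shape[2]
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dy.sum(axis=(0, 2))
        dxhat = dy * g
        dx = (ivar[:, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True))
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0)


class MaxPool1d(Layer):
    """Non-overlapping max pooling with stride = width; trailing remainder
    positions are dropped."""

    def __init__(self, width: int) -> None:
        super().__init__()
        if width < 1:
            raise ValueError("pool width must be >= 1")
        self.width = width

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, L = x.shape
        Lp = L // self.width
        xr = x[:, :, :Lp * self.width].reshape(n, c, Lp, self.width)
        self._argmax = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, Lp = dy.shape
        dxr = np.zeros((n, c, Lp, self.width), dtype=dy.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=3)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, :, :Lp * self.width] = dxr.reshape(n, c, Lp * self.width)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._in_shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None,
                 dtype: np.dtype = np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.params["W"] = (rng.standard_normal(
            (in_features, out_features)) * scale).astype(dtype)
        self.params["b"] = np.zeros(out_features, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["W"].T
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask
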