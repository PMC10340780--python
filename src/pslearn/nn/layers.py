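"""Layers with explicit forward/backward passes.

Conventions: activations are ``(N, C, H, W)`` float arrays (or ``(N, T, C)``
token arrays for attention); each layer caches what its backward pass needs
on ``forward`` and accumulates parameter gradients into ``self.grads`` on
``backward``, returning the gradient w.r.t. its input.  Convolutions are
stride-1, odd-kernel, same-padded; downsampling is done by pooling.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class; parameter-free layers leave ``params``/``grads`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded stride-1 convolution, He-initialized."""

    def __init__(self, cin: int, cout: int, k: int = 3, *, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        assert k % 2 == 1, "odd kernels only"
        self.k, self.pad = k, k // 2
        std = math.sqrt(2.0 / (cin * k * k))
        self.params["W"] = rng.normal(0.0, std, size=(cout, cin, k, k)).astype(dtype)
        self.params["b"] = np.zeros(cout, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
        self._cols = cols
        y = np.tensordot(cols, self.params["W"], axes=([1, 4, 5], [1, 2, 3]))
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2)) + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.pad
        self.grads["b"] = dy.sum(axis=(0, 2, 3))
        self.grads["W"] = np.tensordot(dy, self._cols, axes=([0, 2, 3], [0, 2, 3]))
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p))) if p else dy
        cols2 = sliding_window_view(dyp, (k, k), axis=(2, 3))  # (N,cout,H,W,k,k)
        wf = self.params["W"][:, :, ::-1, ::-1]
        dx = np.tensordot(cols2, wf, axes=([1, 4, 5], [0, 2, 3]))  # (N,H,W,cin)
        self._cols = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling; even spatial dims required. Argmax-based backward is
    deterministic under ties (first maximum wins)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        assert h % 2 == 0 and w % 2 == 0, "MaxPool2 needs even dims"
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        self._idx = win.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        return flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w
        )


class UpsampleNearest2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class GlobalMaxPool(Layer):
    """(N, C, H, W) -> (N, C); gradient routes to the (first) max position."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        self._idx = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h * w), dtype=dy.dtype)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        return flat.reshape(self._shape)


class Linear(Layer):
    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        std = math.sqrt(2.0 / cin)
        self.params["W"] = rng.normal(0.0, std, size=(cin, cout)).astype(dtype)
        self.params["b"] = np.zeros(cout, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        lead = list(range(self._x.ndim - 1))
        self.grads["W"] = np.tensordot(self._x, dy, axes=(lead, lead))
        self.grads["b"] = dy.sum(axis=tuple(lead))
        return dy @ self.params["W"].T


class LayerNorm(Layer):
    """Normalization over the last axis of (N, T, C) token arrays."""

    def __init__(self, c: int, *, dtype=np.float32, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(c, dtype=dtype)
        self.params["beta"] = np.zeros(c, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.params["gamma"] + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c = dy.shape[-1]
        self.grads["gamma"] = (dy * self._xhat).sum(axis=(0, 1))
        self.grads["beta"] = dy.sum(axis=(0, 1))
        dxhat = dy * self.params["gamma"]
        return self._inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=-1, keepdims=True)
        )


class SelfAttention(Layer):
    """Single-head scaled dot-product self-attention over (N, T, C) tokens."""

    def __init__(self, c: int, *, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        std = math.sqrt(1.0 / c)
        for name in ("Wq", "Wk", "Wv", "Wo"):
            self.params[name] = rng.normal(0.0, std, size=(c, c)).astype(dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        self._x = x
        self._q = x @ p["Wq"]
        self._k = x @ p["Wk"]
        self._v = x @ p["Wv"]
        scale = 1.0 / math.sqrt(x.shape[-1])
        s = np.einsum("ntc,nsc->nts", self._q, self._k) * scale
        s -= s.max(axis=-1, keepdims=True)
        e = np.exp(s)
        self._a = e / e.sum(axis=-1, keepdims=True)
        self._z = np.einsum("nts,nsc->ntc", self._a, self._v)
        return self._z @ p["Wo"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p = self.params
        scale = 1.0 / math.sqrt(self._x.shape[-1])
        self.grads["Wo"] = np.einsum("ntc,ntd->cd", self._z, dy)
        dz = dy @ p["Wo"].T
        da = np.einsum("ntc,nsc->nts", dz, self._v)
        dv = np.einsum("nts,ntc->nsc", self._a, dz)
        ds = self._a * (da - (da * self._a).sum(axis=-1, keepdims=True))
        dq = np.einsum("nts,nsc->ntc", ds, self._k) * scale
        dk = np.einsum("nts,ntc->nsc", ds, self._q) * scale
        self.grads["Wq"] = np.einsum("ntc,ntd->cd", self._x, dq)
        self.grads["Wk"] = np.einsum("ntc,ntd->cd", self._x, dk)
        self.grads["Wv"] = np.einsum("ntc,ntd->cd", self._x, dv)
        return dq @ p["Wq"].T + dk @ p["Wk"].T + dv @ p["Wv"].T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy
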