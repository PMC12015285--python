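"""Minimal NumPy neural-network layers with explicit backpropagation.

Data layout is channels-last: feature tensors are ``(B, H, W, C)`` and
vectors ``(B, D)``.  Each layer caches what its backward pass needs during
``forward`` and accumulates parameter gradients in ``.grads`` during
``backward``.  Gradients are exact (verified against finite differences in
the test suite); max-pool splits gradient equally among tied maxima.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "Dense",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Dropout",
    "GlobalAvgPool",
    "softmax",
    "attention_pool",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    """Base class: parameter/gradient dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3×3 (or k×k) convolution with "same" padding and optional dilation.

    A dilation rate ``s`` samples the kernel support at stride ``s``,
    enlarging the receptive field of a size-3 kernel to ``3 + 2(s-1)``
    without extra parameters; ``s=1`` is ordinary convolution.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, dilation: int = 1, rng=None):
        super().__init__()
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        self.cin, self.cout, self.k, self.d = cin, cout, k, dilation
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (k * k * cin))
        self.params["W"] = rng.normal(0.0, scale, size=(k, k, cin, cout))
        self.params["b"] = np.zeros(cout)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, d = self.k, self.d
        p = d * (k // 2)
        self._xpad = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        B, H, W, _ = x.shape
        y = np.broadcast_to(self.params["b"], (B, H, W, self.cout)).copy()
        Wk = self.params["W"]
        for i in range(k):
            for j in range(k):
                sl = self._xpad[:, i * d : i * d + H, j * d : j * d + W, :]
                y += sl @ Wk[i, j]
        self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, d = self.k, self.d
        B, H, W, _ = self._shape
        Wk = self.params["W"]
        dxpad = np.zeros_like(self._xpad)
        self.grads["b"] += dy.sum(axis=(0, 1, 2))
        for i in range(k):
            for j in range(k):
                sl = self._xpad[:, i * d : i * d + H, j * d : j * d + W, :]
                self.grads["W"][i, j] += np.einsum("bhwc,bhwo->co", sl, dy)
                dxpad[:, i * d : i * d + H, j * d : j * d + W, :] += dy @ Wk[i, j].T
        p = d * (k // 2)
        if p == 0:
            return dxpad
        return dxpad[:, p:-p, p:-p, :]


class Dense(Layer):
    def __init__(self, din: int, dout: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / din), size=(din, dout))
        self.params["b"] = np.zeros(dout)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2×2 max pooling; gradient split equally among tied maxima."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, H, W, C = x.shape
        xr = x.reshape(B, H // 2, 2, W // 2, 2, C)
        y = xr.max(axis=(2, 4))
        mask = xr == y[:, :, None, :, None, :]
        self._route = mask / mask.sum(axis=(2, 4), keepdims=True)
        self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dxr = self._route * dy[:, :, None, :, None, :]
        return dxr.reshape(self._shape)


class Upsample2(Layer):
    """Nearest-neighbour ×2 upsampling; gradient sums over 2×2 blocks."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, H, W, C = dy.shape
        return dy.reshape(B, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


class Dropout(Layer):
    """Inverted dropout driven by an externally supplied generator."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, H, W, C = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (H * W), self._shape).copy()


def attention_pool(keys: np.ndarray, query: np.ndarray):
    """Multiplicative (Luong) attention pooling.

    ``keys`` is ``(N, C)`` or ``(B, N, C)``; ``query`` ``(C,)`` or
    ``(B, C)``.  Alignment weights are the softmax of the key–query dot
    products and the context is the weight-averaged key; weights are
    nonnegative and sum to one.
    """
    keys = np.asarray(keys, dtype=float)
    query = np.asarray(query, dtype=float)
    squeeze = keys.ndim == 2
    if squeeze:
        keys = keys[None]
        query = query[None]
    if keys.shape[-1] != query.shape[-1]:
        raise ValueError("key and query widths differ")
    if keys.shape[1] == 0:
        raise ValueError("empty key sequence")
    scores = np.einsum("bnc,bc->bn", keys, query)
    w = softmax(scores, axis=-1)
    context = np.einsum("bn,bnc->bc", w, keys)
    if squeeze:
        return w[0], context[0]
    return w, context


class Attention(Layer):
    """Dot-product attention over flattened spatial positions.

    The query is the global average of the feature map itself, so the full
    gradient has three paths: through the context directly, through the
    alignment weights, and through the query.
    """

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, H, W, C = x.shape
        keys = x.reshape(B, H * W, C)
        q = keys.mean(axis=1)
        scores = np.einsum("bnc,bc->bn", keys, q)
        w = softmax(scores, axis=-1)
        z = np.einsum("bn,bnc->bc", w, keys)
        self._cache = (keys, q, w, x.shape)
        return z

    def backward(self, dz: np.ndarray) -> np.ndarray:
        keys, q, w, shape = self._cache
        B, H, W, C = shape
        N = H * W
        dw = np.einsum("bnc,bc->bn", keys, dz)  # z = Σ w_n k_n
        dscore = w * (dw - np.sum(w * dw, axis=-1, keepdims=True))
        dkeys = w[:, :, None] * dz[:, None, :]  # direct path
        dkeys += dscore[:, :, None] * q[:, None, :]  # via scores, key side
        dq = np.einsum("bn,bnc->bc", dscore, keys)  # via scores, query side
        dkeys += dq[:, None, :] / N  # query is the mean of the keys
        return dkeys.reshape(shape)
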