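"""NumPy layers with forward/backward passes for the waveform-image CNN.

All layers operate on float32 arrays in NCHW layout. Convolutions use
im2col/col2im; pooling stores argmax indices for the backward scatter.
Local response normalization (LRN) normalizes across channels:

    b_i = a_i / (k + (alpha / n) * sum_{j in window(i)} a_j^2)^beta

with an n-channel window centered at i and truncated at the borders.
"""

from __future__ import annotations

import numpy as np

from .arch import ConvSpec, FCSpec, PoolSpec, conv_output_size, pool_output_size

__all__ = ["lrn", "Conv2D", "MaxPool2D", "LRNLayer", "ReLU", "Dropout", "Flatten", "Dense"]


def lrn(
    a: np.ndarray,
    local_size: int = 5,
    alpha: float = 0.0001,
    beta: float = 0.75,
    k: float = 1.0,
) -> np.ndarray:
    """Cross-channel local response normalization (channel axis = 1, or 0 for
    a plain channel vector)."""
    if local_size < 1 or local_size % 2 == 0:
        raise ValueError(f"local_size must be odd and positive, got {local_size}")
    a = np.asarray(a)
    squeeze = a.ndim == 1
    x = a[None, :] if squeeze else a
    ssum = _window_sum(x.astype(np.float64) ** 2, local_size)
    denom = (k + (alpha / local_size) * ssum) ** beta
    out = (x / denom).astype(a.dtype if a.dtype.kind == "f" else np.float64)
    return out[0] if squeeze else out


def _window_sum(x: np.ndarray, local_size: int) -> np.ndarray:
    """Sum over a channel window of local_size centered per channel, truncated."""
    half = (local_size - 1) // 2
    c = x.shape[1]
    out = np.zeros_like(x)
    for d in range(-half, half + 1):
        lo_dst, hi_dst = max(0, -d), min(c, c - d)
        out[:, lo_dst:hi_dst] += x[:, lo_dst + d : hi_dst + d]
    return out


def _im2col(x: np.ndarray, k: int, s: int, p: int) -> tuple[np.ndarray, int, int]:
    n, c, h, w = x.shape
    oh = conv_output_size(h, k, s, p)
    ow = conv_output_size(w, k, s, p)
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + s * oh : s, j : j + s * ow : s]
    return cols.reshape(n, c * k * k, oh * ow), oh, ow


def _col2im(
    dcols: np.ndarray, xshape: tuple[int, ...], k: int, s: int, p: int, oh: int, ow: int
) -> np.ndarray:
    n, c, h, w = xshape
    d6 = dcols.reshape(n, c, k, k, oh, ow)
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += d6[:, :, i, j]
    return dxp[:, :, p : p + h, p : p + w] if p else dxp


class Layer:
    params: tuple = ()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(self, in_channels: int, spec: ConvSpec, rng: np.random.Generator,
                 init_std: float | str, bias_init: float):
        self.spec = spec
        fan_in = in_channels * spec.kernel**2
        std = np.sqrt(2.0 / fan_in) if init_std == "he" else float(init_std)
        self.W = rng.normal(0.0, std, size=(spec.num_output, fan_in)).astype(np.float32)
        self.b = np.full(spec.num_output, bias_init, dtype=np.float32)
        self.in_channels = in_channels
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return ((self.W, self.dW), (self.b, self.db))

    def forward(self, x, train=False):
        s = self.spec
        cols, oh, ow = _im2col(x, s.kernel, s.stride, s.pad)
        self._cache = (cols, x.shape, oh, ow)
        out = np.einsum("fc,ncp->nfp", self.W, cols, optimize=True)
        out += self.b[None, :, None]
        return out.reshape(x.shape[0], s.num_output, oh, ow)

    def backward(self, dout):
        s = self.spec
        cols, xshape, oh, ow = self._cache
        n = dout.shape[0]
        dflat = dout.reshape(n, s.num_output, oh * ow)
        self.dW = np.einsum("nfp,ncp->fc", dflat, cols, optimize=True)
        self.db = dflat.sum(axis=(0, 2))
        dcols = np.einsum("fc,nfp->ncp", self.W, dflat, optimize=True)
        return _col2im(dcols, xshape, s.kernel, s.stride, s.pad, oh, ow)


class MaxPool2D(Layer):
    def __init__(self, spec: PoolSpec):
        self.spec = spec

    def forward(self, x, train=False):
        k, s = self.spec.kernel, self.spec.stride
        n, c, h, w = x.shape
        oh = pool_output_size(h, k, s)
        ow = pool_output_size(w, k, s)
        windows = np.empty((n, c, k * k, oh, ow), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                windows[:, :, i * k + j] = x[:, :, i : i + s * oh : s, j : j + s * ow : s]
        self._arg = windows.argmax(axis=2)
        self._xshape = x.shape
        return windows.max(axis=2)

    def backward(self, dout):
        k, s = self.spec.kernel, self.spec.stride
        n, c, h, w = self._xshape
        oh, ow = dout.shape[2], dout.shape[3]
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            mask = self._arg == idx
            dx[:, :, i : i + s * oh : s, j : j + s * ow : s] += np.where(mask, dout, 0)
        return dx


class LRNLayer(Layer):
    def __init__(self, spec: ConvSpec):
        self.n = spec.lrn_local_size
        self.alpha = spec.lrn_alpha
        self.beta = spec.lrn_beta
        self.k = spec.lrn_k

    def forward(self, x, train=False):
        ssum = _window_sum(x.astype(np.float32) ** 2, self.n)
        scale = self.k + (self.alpha / self.n) * ssum
        self._cache = (x, scale)
        return x * scale**-self.beta

    def backward(self, dout):
        x, scale = self._cache
        # da_j = g_j S_j^-b - (2ab/n) * x_j * window_sum(g x S^(-b-1))_j
        inner = dout * x * scale ** (-self.beta - 1)
        wsum = _window_sum(inner, self.n)
        return dout * scale**-self.beta - (2 * self.alpha * self.beta / self.n) * x * wsum


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, ratio: float, rng: np.random.Generator):
        self.ratio = ratio
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.ratio == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.ratio).astype(x.dtype) / (
            1 - self.ratio
        )
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, spec: FCSpec, rng: np.random.Generator,
                 init_std: float | str, bias_init: float):
        std = np.sqrt(2.0 / in_features) if init_std == "he" else float(init_std)
        self.W = rng.normal(0.0, std, size=(spec.num_output, in_features)).astype(np.float32)
        self.b = np.full(spec.num_output, bias_init, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return ((self.W, self.dW), (self.b, self.db))

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW = dout.T @ self._x
        self.db = dout.sum(axis=0)
        return dout @ self.W


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits for int targets."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), targets], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, (grad / n).astype(np.float32)
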