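"""NumPy layers with explicit forward/backward passes.

Every layer stores its parameters and parameter gradients in ``params`` /
``grads`` dicts keyed by name. Convolution is valid (no padding), stride
1, implemented as an im2col matrix product; max-pooling uses a
window-strided view with floor division on odd sides (the trailing
row/column is dropped, which is what turns a 7x7 map into 3x3 under 2x2
non-overlapping pooling). All arithmetic is float64 so finite-difference
gradient checks are meaningful.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: stateless unless it declares params."""

    name = "layer"

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Valid cross-correlation, stride 1, with per-map bias."""

    def __init__(self, in_channels, out_channels, kernel, rng, name="conv"):
        super().__init__()
        self.name = name
        kh = kw = int(kernel)
        fan_in = in_channels * kh * kw
        limit = np.sqrt(6.0 / fan_in)
        self.params["W"] = rng.uniform(-limit, limit, (out_channels, in_channels, kh, kw))
        self.params["b"] = np.zeros(out_channels)
        self.kernel = kh

    def forward(self, x, train=False):
        W = self.params["W"]
        M, C, kh, kw = W.shape
        B, Cin, H, Wd = x.shape
        if Cin != C:
            raise ValueError(f"{self.name}: input has {Cin} channels, kernel expects {C}")
        if kh > H or kw > Wd:
            raise ValueError(f"{self.name}: {kh}x{kw} filter larger than {H}x{Wd} input")
        Ho, Wo = H - kh + 1, Wd - kw + 1
        cols = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (B,C,Ho,Wo,kh,kw)
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * kh * kw)
        out = cols @ W.reshape(M, -1).T + self.params["b"]
        self._cache = (cols, x.shape)
        return out.transpose(0, 2, 1).reshape(B, M, Ho, Wo)

    def backward(self, dout):
        cols, xshape = self._cache
        W = self.params["W"]
        M, C, kh, kw = W.shape
        B, _, Ho, Wo = dout.shape
        dmat = dout.reshape(B, M, Ho * Wo).transpose(0, 2, 1)  # (B, P, M)
        self.grads["W"] = np.einsum("bpm,bpk->mk", dmat, cols).reshape(W.shape)
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        dcols = (dmat @ W.reshape(M, -1)).reshape(B, Ho, Wo, C, kh, kw)
        dx = np.zeros(xshape)
        for i in range(kh):
            for j in range(kw):
                dx[:, :, i : i + Ho, j : j + Wo] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dx


class MaxPool2D(Layer):
    """Per-channel block maximum; default stride = window (non-overlap)."""

    def __init__(self, window, stride=None, name="maxpool"):
        super().__init__()
        self.name = name
        self.window = int(window)
        self.stride = int(stride) if stride is not None else int(window)

    def forward(self, x, train=False):
        n, s = self.window, self.stride
        B, C, H, W = x.shape
        if n > H or n > W:
            raise ValueError(f"{self.name}: {n}x{n} window larger than {H}x{W} input")
        win = sliding_window_view(x, (n, n), axis=(2, 3))[:, :, ::s, ::s]
        B, C, Ho, Wo = win.shape[:4]
        flat = win.reshape(B, C, Ho, Wo, n * n)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, Ho, Wo)
        return out

    def backward(self, dout):
        idx, xshape, Ho, Wo = self._cache
        n, s = self.window, self.stride
        B, C = xshape[:2]
        dx = np.zeros(xshape)
        b, c, ho, wo = np.ogrid[:B, :C, :Ho, :Wo]
        rows = ho * s + idx // n
        cols = wo * s + idx % n
        np.add.at(dx, (b, c, rows, cols), dout)
        return dx


class ReLU(Layer):
    name = "relu"

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    name = "flatten"

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer: y = x W^T + b."""

    def __init__(self, in_features, out_features, rng, name="fc"):
        super().__init__()
        self.name = name
        limit = np.sqrt(6.0 / in_features)
        self.params["W"] = rng.uniform(-limit, limit, (out_features, in_features))
        self.params["b"] = np.zeros(out_features)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


class Dropout(Layer):
    """Inverted dropout; active only in train mode."""

    def __init__(self, ratio, rng, name="dropout"):
        super().__init__()
        if not 0.0 <= ratio < 1.0:
            raise ValueError("dropout ratio must be in [0, 1)")
        self.name = name
        self.ratio = ratio
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.ratio == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.ratio
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(y)
    loss = -float(np.log(np.clip(p[np.arange(n), y], 1e-300, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n
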