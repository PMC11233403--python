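"""Minimal CNN building blocks on numpy: conv, pool, upsample, Adam/Nadam.

Activations are (H, W, C) float32; kernels are (k, k, Cin, Cout) with "same"
zero padding.  Each layer caches what its backward pass needs; backward
returns the gradient w.r.t. its input and accumulates parameter gradients.
This is deliberately small — just enough machinery to train UNet-style
encoder–decoder segmenters on fixture-sized images on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv:
    """k×k convolution with same padding (k odd)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        # He initialization for ReLU networks
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.w = (rng.standard_normal((k, k, c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h, w, c_in = x.shape
        k, p = self.k, self.k // 2
        if p:
            xp = np.zeros((h + 2 * p, w + 2 * p, c_in), dtype=np.float32)
            xp[p:-p, p:-p] = x
        else:
            xp = x
        # (h, w, c_in, k, k) -> (h*w, k*k*c_in) with (ki, kj, c) ordering
        win = sliding_window_view(xp, (k, k), axis=(0, 1))
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 4, 2)).reshape(h * w, k * k * c_in)
        self._cols = cols
        self._shape = (h, w, c_in)
        out = cols @ self.w.reshape(k * k * c_in, -1) + self.b
        return out.reshape(h, w, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w, c_in = self._shape
        k, p = self.k, self.k // 2
        c_out = self.b.size
        dyf = dy.reshape(h * w, c_out)
        self.dw += (self._cols.T @ dyf).reshape(self.w.shape)
        self.db += dyf.sum(axis=0)
        dcols = dyf @ self.w.reshape(k * k * c_in, c_out).T
        dcols = dcols.reshape(h, w, k, k, c_in)
        dxp = np.zeros((h + 2 * p, w + 2 * p, c_in), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[i : i + h, j : j + w] += dcols[:, :, i, j]
        return dxp[p : p + h, p : p + w] if p else dxp


class ReLU:
    params = ()

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0))

    def backward(self, dy):
        return np.where(self._mask, dy, np.float32(0))


class MaxPool2:
    """2×2 max pooling, stride 2; input sides must be even."""

    params = ()

    def forward(self, x):
        h, w, c = x.shape
        xr = x.reshape(h // 2, 2, w // 2, 2, c)
        flat = xr.transpose(0, 2, 4, 1, 3).reshape(h // 2, w // 2, c, 4)
        self._arg = flat.argmax(axis=3)
        self._shape = x.shape
        return flat.max(axis=3)

    def backward(self, dy):
        h, w, c = self._shape
        dflat = np.zeros((h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(dflat, self._arg[..., None], dy[..., None], axis=3)
        return (
            dflat.reshape(h // 2, w // 2, c, 2, 2)
            .transpose(0, 3, 1, 4, 2)
            .reshape(h, w, c)
        )


class Upsample2:
    """Nearest-neighbor 2× upsampling; backward sums each 2×2 block."""

    params = ()

    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=0), 2, axis=1)

    def backward(self, dy):
        h, w, c = dy.shape
        return dy.reshape(h // 2, 2, w // 2, 2, c).sum(axis=(1, 3))


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray, class_weights=None):
    """Mean per-pixel cross entropy; returns (loss, dlogits, probs)."""
    z = logits - logits.max(axis=2, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=2, keepdims=True)
    h, w, k = logits.shape
    flat = probs.reshape(-1, k)
    idx = labels.ravel()
    picked = np.clip(flat[np.arange(flat.shape[0]), idx], 1e-12, None)
    if class_weights is None:
        weights = np.ones_like(picked, dtype=np.float32)
    else:
        weights = np.asarray(class_weights, dtype=np.float32)[idx]
    wsum = weights.sum()
    loss = float(-(weights * np.log(picked)).sum() / wsum)
    dflat = flat * weights[:, None]
    dflat[np.arange(flat.shape[0]), idx] -= weights
    dlogits = (dflat / wsum).reshape(h, w, k).astype(np.float32)
    return loss, dlogits, probs


class AdaptiveMoments:
    """Adam / Nadam optimizer over a list of (param, grad) pairs.

    Both rules share the same first/second moment state, so the training
    schedule can alternate between them mid-run.
    """

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self, rule: str = "adam"):
        if rule not in ("adam", "nadam"):
            raise ValueError(f"unknown update rule {rule!r}")
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            v_hat = self.v[i] / (1 - b2**self.t)
            if rule == "adam":
                m_hat = self.m[i] / (1 - b1**self.t)
            else:  # Nadam: Nesterov look-ahead on the first moment
                m_hat = (b1 * self.m[i] / (1 - b1 ** (self.t + 1))
                         + (1 - b1) * g / (1 - b1**self.t))
            p -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(p.dtype)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0
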