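"""Minimal NumPy convolutional-network engine.

Implements exactly the pieces the observer model needs — strided 2-D
convolution, ReLU, 2x2 max pooling, locally connected (per-position kernel)
convolution, bilinear resampling, and a dense head — each with a hand-written
backward pass.  Backpropagation serves two purposes here: training the small
observer, and computing the input-gradient sensitivity maps used for
receptive-field estimation.

Conventions
-----------
* Activations are ``float32`` arrays in NHWC layout ``(batch, rows, cols,
  channels)``; coordinates are 0-based ``(row, col)``.
* Each layer caches what its backward pass needs during ``forward``; calls
  are strictly ``forward``-then-``backward`` (no concurrent use of one layer
  instance).
* Max-pool ties route gradient to every tied element.  Ties only occur at
  exactly-equal activations (measure zero after training), and tied zeros are
  subsequently masked by the upstream ReLU, so this has no practical effect.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class: stateless unless it has weights."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self):
        return []

    def grads(self):
        return []


class Conv2d(Layer):
    """Strided 2-D convolution (cross-correlation) with optional bias.

    Weights have shape ``(kh, kw, c_in, c_out)``.
    """

    def __init__(self, kh, kw, c_in, c_out, stride=1, pad=0, bias=True, rng=None):
        self.kh, self.kw = int(kh), int(kw)
        self.stride, self.pad = int(stride), int(pad)
        rng = rng or np.random.default_rng(0)
        fan_in = kh * kw * c_in
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = (rng.standard_normal((kh, kw, c_in, c_out)) * scale).astype(DTYPE)
        self.b = np.zeros(c_out, DTYPE) if bias else None
        self.dW = None
        self.db = None
        self._cache = None

    def out_shape(self, H, W):
        s, p = self.stride, self.pad
        return (H + 2 * p - self.kh) // s + 1, (W + 2 * p - self.kw) // s + 1

    def forward(self, x):
        n, H, W, ci = x.shape
        s, p = self.stride, self.pad
        Ho, Wo = self.out_shape(H, W)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        y = np.zeros((n, Ho, Wo, self.W.shape[3]), DTYPE)
        for u in range(self.kh):
            for v in range(self.kw):
                xs = xp[:, u : u + s * (Ho - 1) + 1 : s, v : v + s * (Wo - 1) + 1 : s, :]
                y += xs @ self.W[u, v]
        if self.b is not None:
            y += self.b
        self._cache = (xp, x.shape)
        return y

    def backward(self, dy):
        xp, xshape = self._cache
        n, H, W, ci = xshape
        s, p = self.stride, self.pad
        Ho, Wo = dy.shape[1], dy.shape[2]
        self.dW = np.zeros_like(self.W)
        dxp = np.zeros_like(xp)
        dyf = dy.reshape(-1, dy.shape[3])
        for u in range(self.kh):
            for v in range(self.kw):
                sl = (
                    slice(None),
                    slice(u, u + s * (Ho - 1) + 1, s),
                    slice(v, v + s * (Wo - 1) + 1, s),
                    slice(None),
                )
                xs = xp[sl]
                self.dW[u, v] = xs.reshape(-1, ci).T @ dyf
                dxp[sl] += dy @ self.W[u, v].T
        if self.b is not None:
            self.db = dy.sum(axis=(0, 1, 2))
        return dxp[:, p : p + H, p : p + W, :] if p else dxp

    def params(self):
        return [self.W] if self.b is None else [self.W, self.b]

    def grads(self):
        return [self.dW] if self.b is None else [self.dW, self.db]


class LocallyConnected2d(Layer):
    """Convolution-like layer with an independent kernel at every output
    position; weights ``(Ho, Wo, kh, kw, c_in, c_out)``.

    Used by the counterfactual rewiring variants, where the kernel must vary
    with the unit's distance to the locus of attention.  No bias (variants
    inherit the base model's bias through a separate channel-bias term).
    """

    def __init__(self, W, stride=1, pad=0, bias=None):
        self.W = np.asarray(W, DTYPE)
        self.stride, self.pad = int(stride), int(pad)
        self.b = None if bias is None else np.asarray(bias, DTYPE)
        self._cache = None

    @classmethod
    def from_conv(cls, conv: Conv2d, Ho, Wo):
        """Tile a shared conv kernel to per-position kernels (identity op)."""
        W = np.broadcast_to(conv.W, (Ho, Wo) + conv.W.shape).copy()
        return cls(W, stride=conv.stride, pad=conv.pad,
                   bias=None if conv.b is None else conv.b.copy())

    def forward(self, x):
        n, H, W_, ci = x.shape
        s, p = self.stride, self.pad
        Ho, Wo, kh, kw = self.W.shape[:4]
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        y = np.zeros((n, Ho, Wo, self.W.shape[5]), DTYPE)
        for u in range(kh):
            for v in range(kw):
                xs = xp[:, u : u + s * (Ho - 1) + 1 : s, v : v + s * (Wo - 1) + 1 : s, :]
                # (n,Ho,Wo,ci) x (Ho,Wo,ci,co) -> (n,Ho,Wo,co)
                y += np.einsum("nhwc,hwco->nhwo", xs, self.W[:, :, u, v])
        if self.b is not None:
            y += self.b
        self._cache = (xp, x.shape)
        return y

    def backward(self, dy):
        xp, xshape = self._cache
        n, H, W_, ci = xshape
        s, p = self.stride, self.pad
        Ho, Wo, kh, kw = self.W.shape[:4]
        dxp = np.zeros_like(xp)
        for u in range(kh):
            for v in range(kw):
                sl = (
                    slice(None),
                    slice(u, u + s * (Ho - 1) + 1, s),
                    slice(v, v + s * (Wo - 1) + 1, s),
                    slice(None),
                )
                dxp[sl] += np.einsum("nhwo,hwco->nhwc", dy, self.W[:, :, u, v])
        return dxp[:, p : p + H, p : p + W_, :] if p else dxp


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, np.zeros((), DTYPE))

    def backward(self, dy):
        return np.where(self._mask, dy, np.zeros((), DTYPE))


class MaxPool2x2(Layer):
    """2x2, stride-2 max pooling; odd trailing rows/cols are dropped (the
    standard floor convention, needed when an image quadrant is processed
    standalone and a block output side is odd)."""

    def forward(self, x):
        n, H, W, c = x.shape
        self._trim = (H - H % 2, W - W % 2)
        Ht, Wt = self._trim
        xr = x[:, :Ht, :Wt].reshape(n, Ht // 2, 2, Wt // 2, 2, c)
        y = xr.max(axis=(2, 4))
        self._mask = xr == y[:, :, None, :, None, :]
        self._shape = x.shape
        return y

    def backward(self, dy):
        n, H, W, c = self._shape
        Ht, Wt = self._trim
        dxr = self._mask * dy[:, :, None, :, None, :]
        dx = np.zeros((n, H, W, c), DTYPE)
        dx[:, :Ht, :Wt] = dxr.reshape(n, Ht, Wt, c)
        return dx


class BilinearResample(Layer):
    """Replace activation at grid position q with the bilinearly interpolated
    activation at q + shift(q); sample coordinates outside the map are clamped
    to the border.

    ``src_rows``/``src_cols`` are float arrays of shape (H, W) giving, for each
    output position, the source sampling coordinate.
    """

    def __init__(self, src_rows, src_cols):
        self.src_rows = np.asarray(src_rows, np.float64)
        self.src_cols = np.asarray(src_cols, np.float64)
        self._prep = None

    def _prepare(self, H, W):
        r = np.clip(self.src_rows, 0.0, H - 1.0)
        c = np.clip(self.src_cols, 0.0, W - 1.0)
        r0 = np.floor(r).astype(np.int64)
        c0 = np.floor(c).astype(np.int64)
        r1 = np.minimum(r0 + 1, H - 1)
        c1 = np.minimum(c0 + 1, W - 1)
        fr = (r - r0).astype(DTYPE)
        fc = (c - c0).astype(DTYPE)
        corners = []
        for ri, wr in ((r0, 1 - fr), (r1, fr)):
            for ci, wc in ((c0, 1 - fc), (c1, fc)):
                corners.append((ri * W + ci, (wr * wc)))
        self._prep = (H, W, corners)

    def forward(self, x):
        n, H, W, c = x.shape
        if self._prep is None or self._prep[0] != H or self._prep[1] != W:
            self._prepare(H, W)
        _, _, corners = self._prep
        xf = x.reshape(n, H * W, c)
        y = np.zeros_like(x)
        for idx, w in corners:
            y += xf[:, idx.ravel(), :].reshape(x.shape) * w.reshape(1, H, W, 1)
        self._xshape = x.shape
        return y

    def backward(self, dy):
        n, H, W, c = self._xshape
        _, _, corners = self._prep
        # scatter-add with the flat spatial axis first
        dxf = np.zeros((H * W, n * c), DTYPE)
        dyt = dy.transpose(1, 2, 0, 3).reshape(H * W, n * c)
        for idx, w in corners:
            np.add.at(dxf, idx.ravel(), dyt * w.reshape(H * W, 1))
        return dxf.reshape(H, W, n, c).transpose(2, 0, 1, 3)


class Linear(Layer):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = (rng.standard_normal((n_in, n_out)) / np.sqrt(n_in)).astype(DTYPE)
        self.b = np.zeros(n_out, DTYPE)
        self.dW = None
        self.db = None

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy loss and its gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-12))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


class Adam:
    """Adam over a list of layers' parameters."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params()]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in l.params()] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params()] for l in self.layers]

    def step(self):
        self.t += 1
        corr1 = 1 - self.b1**self.t
        corr2 = 1 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params(), layer.grads())):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
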