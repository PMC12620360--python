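"""Minimal trainable layer stack in NumPy (float32).

Provides exactly the primitives the classifier needs — 1-D convolution
(FFT-based, 'same' padding, stride 1), batch normalization, ELU, average
pooling, linear/projection layers, layer normalization, dropout, scaled
dot-product attention, softmax cross-entropy, and AdamW — each with an
explicit backward pass.  Shapes follow the (batch, channels, time)
convention for convolutional tensors and (batch, tokens, dim) for attention.
"""

from __future__ import annotations

import numba
import numpy as np
from scipy import fft as sfft

DTYPE = np.float32


@numba.njit(cache=False)
def _elu_kernel(x, alpha):
    """Fused ELU: returns (y, dy/dx) in one pass over the flattened array."""
    x1 = x.ravel()
    y = np.empty_like(x1)
    deriv = np.empty_like(x1)
    for i in range(x1.size):
        v = x1[i]
        if v > 0:
            y[i] = v
            deriv[i] = 1.0
        else:
            e = alpha * (np.exp(v) - 1.0)
            y[i] = e
            deriv[i] = e + alpha
    return y.reshape(x.shape), deriv.reshape(x.shape)


class Parameter:
    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base layer: params is a list of Parameter, buffers a dict of
    non-trainable state (e.g. batch-norm running statistics)."""

    def __init__(self):
        self.params: list = []
        self.buffers: dict = {}

    def forward(self, x, training=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


# ---------------------------------------------------------------------------
# FFT cross-correlation helpers ('same' padding, stride 1)
# ---------------------------------------------------------------------------

class Conv1d(Layer):
    """1-D convolution (cross-correlation), stride 1, 'same' zero padding.

    Implemented by circular FFT correlation at a single transform length
    n >= L + K - 1, which leaves every output window the forward pass and
    both gradients need free of circular aliasing; the input spectrum is
    cached from the forward pass and reused for the kernel gradient.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng, name="conv",
                 input_layer: bool = False):
        super().__init__()
        self.kernel = kernel
        self.pad_left = (kernel - 1) // 2
        # input_layer skips the (unused) gradient w.r.t. the network input
        self.input_layer = input_layer
        bound = 1.0 / np.sqrt(c_in * kernel)
        self.w = Parameter(f"{name}.w",
                           rng.uniform(-bound, bound, (c_out, c_in, kernel)))
        self.b = Parameter(f"{name}.b", rng.uniform(-bound, bound, c_out))
        self.params = [self.w, self.b]

    def _cmul(self, a, b, spec):
        """Complex contraction over the channel axis; single-channel inputs
        reduce to a broadcast product."""
        if a.shape[1] == 1 and spec == "bif,oif->bof":
            return a[:, 0, :][:, None, :] * b[:, 0, :][None, :, :]
        return np.einsum(spec, a, b, optimize=True)

    def forward(self, x, training=False):
        if self.kernel == 1:
            self._x = x
            y = np.einsum("bil,oi->bol", x, self.w.value[:, :, 0], optimize=True)
            return y + self.b.value[None, :, None]
        L = x.shape[-1]
        K = self.kernel
        pl = self.pad_left
        n = sfft.next_fast_len(L + K - 1)
        self._L, self._n = L, n
        self._xf = sfft.rfft(x, n, axis=-1)
        self._wf = sfft.rfft(self.w.value, n, axis=-1)
        # y[t] = sum_k w[k] x[t+k-pl]: circular cross-correlation of x by w,
        # read at indices (t - pl) mod n
        c = sfft.irfft(
            self._cmul(self._xf, np.conj(self._wf), "bif,oif->bof"), n, axis=-1
        )
        y = np.concatenate([c[..., n - pl:], c[..., : L - pl]], axis=-1) \
            if pl else c[..., :L]
        return y.astype(DTYPE, copy=False) + self.b.value[None, :, None]

    def backward(self, dy):
        dy = np.asarray(dy, dtype=DTYPE)
        self.b.grad += dy.sum(axis=(0, 2))
        if self.kernel == 1:
            self.w.grad += np.einsum("bol,bil->oi", dy, self._x,
                                     optimize=True)[:, :, None]
            return np.einsum("bol,oi->bil", dy, self.w.value[:, :, 0],
                             optimize=True)
        L, n = self._L, self._n
        K = self.kernel
        pl = self.pad_left
        dyf = sfft.rfft(dy, n, axis=-1)
        dx = None
        if not self.input_layer:
            # dx[a] = sum_k w[k] dy[a+pl-k]: circular convolution, read at a+pl
            z = sfft.irfft(
                np.einsum("bof,oif->bif", dyf, self._wf, optimize=True),
                n, axis=-1,
            )
            dx = np.ascontiguousarray(z[..., pl:pl + L], dtype=DTYPE)
        # dw[k] = sum_t x[t+k-pl] dy[t]: circular cross-correlation of x by
        # dy, read at (k - pl) mod n
        zw = sfft.irfft(
            np.einsum("bif,bof->oif", self._xf, np.conj(dyf), optimize=True),
            n, axis=-1,
        )
        dw = np.concatenate([zw[..., n - pl:], zw[..., :K - pl]], axis=-1) \
            if pl else zw[..., :K]
        self.w.grad += dw
        return dx


class BatchNorm1d(Layer):
    """Batch normalization over (batch, time) per channel; accepts (B, C, L)
    or (B, C).  Normalizes with the biased batch variance; running variance
    is stored unbiased (momentum 0.1, eps 1e-5)."""

    def __init__(self, c: int, momentum=0.1, eps=1e-5, name="bn"):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(f"{name}.gamma", np.ones(c))
        self.beta = Parameter(f"{name}.beta", np.zeros(c))
        self.params = [self.gamma, self.beta]
        self.buffers = {
            "running_mean": np.zeros(c, dtype=DTYPE),
            "running_var": np.ones(c, dtype=DTYPE),
        }

    def _bshape(self, x):
        return (1, -1, 1) if x.ndim == 3 else (1, -1)

    @staticmethod
    def _channel_dot(a, b):
        spec = "bcl,bcl->c" if a.ndim == 3 else "bc,bc->c"
        return np.einsum(spec, a, b, optimize=True)

    def forward(self, x, training=False):
        """Applied as the single fused affine pass y = a*x + b with
        per-channel a = gamma/std and b = beta - a*mean (x is cached; the
        normalized activations are reconstructed on demand in backward)."""
        axes = (0, 2) if x.ndim == 3 else (0,)
        self._axes = axes
        self._training = training
        self._x = x
        if training:
            mean = x.mean(axis=axes, dtype=np.float64)
            sumsq = self._channel_dot(x, x)
            n = x.size / mean.size
            var = np.maximum(sumsq / n - mean**2, 0.0)
            m = self.momentum
            self.buffers["running_mean"] = (
                (1 - m) * self.buffers["running_mean"] + m * mean
            ).astype(DTYPE)
            unbiased = var * n / max(n - 1, 1)
            self.buffers["running_var"] = (
                (1 - m) * self.buffers["running_var"] + m * unbiased
            ).astype(DTYPE)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        shape = self._bshape(x)
        self._mean = mean.astype(DTYPE)
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        a = self.gamma.value * self._inv_std
        b = self.beta.value - a * self._mean
        return a.reshape(shape) * x + b.reshape(shape)

    def backward(self, dy):
        axes = self._axes
        shape = self._bshape(dy)
        dbeta = dy.sum(axis=axes)
        # dgamma = sum dy * xhat, computed from the cached raw input
        dgamma = self._inv_std * (self._channel_dot(dy, self._x)
                                  - self._mean * dbeta)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        a = self.gamma.value * self._inv_std
        if not self._training:
            return dy * a.reshape(shape)
        m = dy.size / dbeta.size
        # dx = a*dy + bx*x + c with per-channel coefficients (xhat expanded)
        bx = -a * self._inv_std * dgamma / m
        c = a * (self._mean * self._inv_std * dgamma - dbeta) / m
        return (a.reshape(shape) * dy + bx.reshape(shape) * self._x
                + c.reshape(shape))


class ELU(Layer):
    def __init__(self, alpha=1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False):
        y, self._deriv = _elu_kernel(
            np.ascontiguousarray(x, dtype=DTYPE), DTYPE(self.alpha)
        )
        return y

    def backward(self, dy):
        return dy * self._deriv


class AvgPool1d(Layer):
    """Non-overlapping average pooling (length == stride); trailing samples
    that do not fill a window are dropped (floor division)."""

    def __init__(self, size: int):
        super().__init__()
        if size < 1:
            raise ValueError("pool size must be >= 1")
        self.size = size

    def forward(self, x, training=False):
        B, C, L = x.shape
        n_out = L // self.size
        self._in_len = L
        return x[..., : n_out * self.size].reshape(B, C, n_out, self.size).mean(-1)

    def backward(self, dy):
        B, C, n_out = dy.shape
        dx = np.zeros((B, C, self._in_len), dtype=DTYPE)
        dx[..., : n_out * self.size].reshape(B, C, n_out, self.size)[...] = \
            (dy / self.size)[..., None]
        return dx


class Linear(Layer):
    """Affine map over the last axis; accepts any leading shape.

    bias=False is used for key projections, where a bias shifts every
    attention score in a row equally and is exactly inert under softmax."""

    def __init__(self, d_in: int, d_out: int, rng, name="linear", bias=True):
        super().__init__()
        bound = 1.0 / np.sqrt(d_in)
        self.w = Parameter(f"{name}.w", rng.uniform(-bound, bound, (d_in, d_out)))
        self.b = Parameter(f"{name}.b", rng.uniform(-bound, bound, d_out)) \
            if bias else None
        self.params = [self.w] + ([self.b] if bias else [])

    def forward(self, x, training=False):
        self._x = x
        y = x @ self.w.value
        return y + self.b.value if self.b is not None else y

    def backward(self, dy):
        dy = np.asarray(dy, dtype=DTYPE)
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.w.grad += x2.T @ dy2
        if self.b is not None:
            self.b.grad += dy2.sum(axis=0)
        return dy @ self.w.value.T


class LayerNorm(Layer):
    def __init__(self, d: int, eps=1e-5, name="ln"):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(f"{name}.gamma", np.ones(d))
        self.beta = Parameter(f"{name}.beta", np.zeros(d))
        self.params = [self.gamma, self.beta]

    def forward(self, x, training=False):
        mean = x.mean(-1, keepdims=True)
        var = x.var(-1, keepdims=True)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        return (self.gamma.value * self._xhat + self.beta.value).astype(DTYPE)

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.gamma.grad += (dy * self._xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        d = dy.shape[-1]
        dxhat = dy * self.gamma.value
        return self._inv_std * (
            dxhat
            - dxhat.mean(-1, keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(-1, keepdims=True)
        )


class Dropout(Layer):
    """Inverted dropout driven by an explicit generator for reproducibility."""

    def __init__(self, p: float, rng):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


# ---------------------------------------------------------------------------
# Scaled dot-product attention
# ---------------------------------------------------------------------------

def attention_forward(Q, K, V):
    """softmax(Q K^T / sqrt(d_k)) V for batched (B, T, d) tensors.

    Returns (attended (B, T, d_v), map (B, T, T), cache)."""
    dk = Q.shape[-1]
    scale = 1.0 / np.sqrt(dk)
    scores = np.einsum("btd,bsd->bts", Q, K, optimize=True) * scale
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    A = e / e.sum(axis=-1, keepdims=True)
    out = np.einsum("bts,bsv->btv", A, V, optimize=True)
    return out.astype(DTYPE), A.astype(DTYPE), (Q, K, V, A, scale)


def attention_backward(dout, cache):
    Q, K, V, A, scale = cache
    dV = np.einsum("bts,btv->bsv", A, dout, optimize=True)
    dA = np.einsum("btv,bsv->bts", dout, V, optimize=True)
    dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
    dQ = np.einsum("bts,bsd->btd", dS, K, optimize=True) * scale
    dK = np.einsum("bts,btd->bsd", dS, Q, optimize=True) * scale
    return dQ.astype(DTYPE), dK.astype(DTYPE), dV.astype(DTYPE)


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------

def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits, labels):
    """Mean cross-entropy on logits; returns (loss, dlogits)."""
    labels = np.asarray(labels)
    p = softmax(logits.astype(np.float64))
    n = len(labels)
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-12)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(DTYPE)


class AdamW:
    """AdamW with decoupled weight decay (applied to every parameter)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.01):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * self.weight_decay * p.value
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
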