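"""Minimal feed-forward/backprop engine for the spectral networks.

Implements exactly the layer set needed by the 1D-CNN and CNN-Transformer
classifiers: 1-D convolution (same padding), batch normalization, ReLU,
max pooling, dense layers, dropout, layer normalization, sinusoidal positional
encoding, multi-head scaled-dot-product self-attention, and a post-norm
transformer encoder block, trained with Adam on softmax cross-entropy.

Everything is plain numpy with explicit backward passes; all randomness
(initialisation, shuffling, dropout) flows from one ``numpy.random.Generator``
so training is bit-reproducible for a fixed seed in single-threaded runs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense", "Conv1d", "BatchNorm1d", "ReLU", "MaxPool1d", "Flatten",
    "Dropout", "LayerNorm", "PositionalEncoding", "MultiHeadSelfAttention",
    "TransformerEncoderLayer", "PatchEmbed", "ToChannels", "Network",
    "Adam", "softmax", "cross_entropy",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(p[np.arange(n), targets] + 1e-12).mean()
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(loss), grad / n


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base: parameters and their gradients are parallel lists."""

    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = _glorot(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._shape = x.shape
        self._x = x.reshape(-1, self._shape[-1])
        return (self._x @ self.W + self.b).reshape(*self._shape[:-1], -1)

    def backward(self, g):
        g2 = g.reshape(-1, g.shape[-1])
        self.grads[0][...] = self._x.T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        return (g2 @ self.W.T).reshape(self._shape)


class Conv1d(Layer):
    """1-D convolution with 'same' zero padding, stride 1, over (N, C, L)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel
        self.W = _glorot(rng, fan_in, c_out, (c_out, fan_in))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        n, c, L = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        cols = np.stack([xp[:, :, i : i + L] for i in range(self.k)], axis=2)
        self._cols = cols.reshape(n, c * self.k, L)
        self._L, self._pad = L, p
        out = np.einsum("fk,nkl->nfl", self.W, self._cols, optimize=True)
        return out + self.b[None, :, None]

    def backward(self, g):
        self.grads[0][...] = np.einsum("nfl,nkl->fk", g, self._cols, optimize=True)
        self.grads[1][...] = g.sum(axis=(0, 2))
        gcols = np.einsum("fk,nfl->nkl", self.W, g, optimize=True)
        n = g.shape[0]
        L, p = self._L, self._pad
        gcols = gcols.reshape(n, self.c_in, self.k, L)
        gx = np.zeros((n, self.c_in, L + 2 * p))
        for i in range(self.k):
            gx[:, :, i : i + L] += gcols[:, :, i, :]
        return gx[:, :, p : p + L] if p else gx


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (N, C, L)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean += self.momentum * (mean - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, g):
        xhat = self._xhat
        self.grads[0][...] = (g * xhat).sum(axis=(0, 2))
        self.grads[1][...] = g.sum(axis=(0, 2))
        m = g.shape[0] * g.shape[2]
        gx = (self.gamma / self._std)[None, :, None] * (
            g
            - g.mean(axis=(0, 2), keepdims=True)
            - xhat * (g * xhat).mean(axis=(0, 2), keepdims=True)
        )
        return gx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool1d(Layer):
    """Width-2, stride-2 max pooling over (N, C, L); an odd tail is dropped."""

    def forward(self, x, train):
        n, c, L = x.shape
        self._L = L
        L2 = L // 2
        xr = x[:, :, : 2 * L2].reshape(n, c, L2, 2)
        self._arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, g):
        n, c, L2 = g.shape
        gx = np.zeros((n, c, self._L))
        idx = 2 * np.arange(L2)[None, None, :] + self._arg
        np.put_along_axis(gx, idx, g, axis=2)
        return gx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class LayerNorm(Layer):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.eps = eps

    def forward(self, x, train):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, g):
        xhat = self._xhat
        axes = tuple(range(g.ndim - 1))
        self.grads[0][...] = (g * xhat).sum(axis=axes)
        self.grads[1][...] = g.sum(axis=axes)
        gh = g * self.gamma
        return (
            gh - gh.mean(axis=-1, keepdims=True) - xhat * (gh * xhat).mean(axis=-1, keepdims=True)
        ) / self._std


class PositionalEncoding(Layer):
    """Fixed sinusoidal position codes added to token embeddings (N, T, D)."""

    def __init__(self, n_tokens: int, d_model: int):
        super().__init__()
        pos = np.arange(n_tokens)[:, None]
        i = np.arange(d_model)[None, :]
        angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
        pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
        self.pe = pe

    def forward(self, x, train):
        return x + self.pe[None, : x.shape[1], :]

    def backward(self, g):
        return g


def scaled_dot_attention_forward(q, k, v):
    """softmax(q k^T / sqrt(d_k)) v with cached weights; q,k,v: (..., T, d)."""
    d_k = q.shape[-1]
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(d_k)
    A = softmax(scores, axis=-1)
    return A @ v, A


class MultiHeadSelfAttention(Layer):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d, self.h = d_model, n_heads
        self.dh = d_model // n_heads
        self.Wq = _glorot(rng, d_model, d_model, (d_model, d_model))
        self.Wk = _glorot(rng, d_model, d_model, (d_model, d_model))
        self.Wv = _glorot(rng, d_model, d_model, (d_model, d_model))
        self.Wo = _glorot(rng, d_model, d_model, (d_model, d_model))
        self.bq, self.bk, self.bv, self.bo = (np.zeros(d_model) for _ in range(4))
        self.params = [self.Wq, self.Wk, self.Wv, self.Wo, self.bq, self.bk, self.bv, self.bo]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.last_attention: np.ndarray | None = None  # (N, H, T, T), introspection

    def _split(self, z, n, t):
        return z.reshape(n, t, self.h, self.dh).transpose(0, 2, 1, 3)

    def forward(self, x, train):
        n, t, _ = x.shape
        self._x = x
        q = self._split(x @ self.Wq + self.bq, n, t)
        k = self._split(x @ self.Wk + self.bk, n, t)
        v = self._split(x @ self.Wv + self.bv, n, t)
        out, A = scaled_dot_attention_forward(q, k, v)
        self._q, self._k, self._v, self._A = q, k, v, A
        self.last_attention = A
        self._concat = out.transpose(0, 2, 1, 3).reshape(n, t, self.d)
        return self._concat @ self.Wo + self.bo

    def backward(self, g):
        n, t, _ = g.shape
        x2 = self._x.reshape(-1, self.d)
        gc = g.reshape(-1, self.d)
        self.grads[3][...] = self._concat.reshape(-1, self.d).T @ gc  # Wo
        self.grads[7][...] = gc.sum(axis=0)  # bo
        g_out = (gc @ self.Wo.T).reshape(n, t, self.h, self.dh).transpose(0, 2, 1, 3)

        A, q, k, v = self._A, self._q, self._k, self._v
        gA = g_out @ np.swapaxes(v, -1, -2)
        gv = np.swapaxes(A, -1, -2) @ g_out
        gS = A * (gA - (gA * A).sum(axis=-1, keepdims=True))
        gS = gS / np.sqrt(self.dh)
        gq = gS @ k
        gk = np.swapaxes(gS, -1, -2) @ q

        def merge(z):
            return z.transpose(0, 2, 1, 3).reshape(-1, self.d)

        gq, gk, gv = merge(gq), merge(gk), merge(gv)
        self.grads[0][...] = x2.T @ gq
        self.grads[1][...] = x2.T @ gk
        self.grads[2][...] = x2.T @ gv
        self.grads[4][...] = gq.sum(axis=0)
        self.grads[5][...] = gk.sum(axis=0)
        self.grads[6][...] = gv.sum(axis=0)
        gx = gq @ self.Wq.T + gk @ self.Wk.T + gv @ self.Wv.T
        return gx.reshape(n, t, self.d)


class TransformerEncoderLayer(Layer):
    """Post-norm encoder block: LN(x + MHSA(x)), then LN(x + FFN(x))."""

    def __init__(self, d_model: int, n_heads: int, ffn_width: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ff1 = Dense(d_model, ffn_width, rng)
        self.relu = ReLU()
        self.ff2 = Dense(ffn_width, d_model, rng)
        self.ln2 = LayerNorm(d_model)
        self.drop = Dropout(dropout, rng)
        self._sub = [self.attn, self.ln1, self.ff1, self.relu, self.ff2, self.ln2, self.drop]
        self.params = [p for s in self._sub for p in s.params]
        self.grads = [g for s in self._sub for g in s.grads]

    def forward(self, x, train):
        a = self.drop.forward(self.attn.forward(x, train), train)
        h = self.ln1.forward(x + a, train)
        f = self.ff2.forward(self.relu.forward(self.ff1.forward(h, train), train), train)
        return self.ln2.forward(h + f, train)

    def backward(self, g):
        g = self.ln2.backward(g)
        gf = self.ff1.backward(self.relu.backward(self.ff2.backward(g)))
        g = self.ln1.backward(g + gf)
        ga = self.attn.backward(self.drop.backward(g))
        return g + ga


class PatchEmbed(Layer):
    """(N, 1, L) spectra -> (N, T, patch) tokens of contiguous band patches.

    The tail is zero-padded when the band count is not a multiple of the patch
    width, so CARS/UVE-sized inputs embed without dropping bands.
    """

    def __init__(self, patch: int):
        super().__init__()
        self.patch = patch

    def forward(self, x, train):
        n, c, L = x.shape
        if c != 1:
            raise ValueError("PatchEmbed expects single-channel spectra")
        self._L = L
        t = -(-L // self.patch)
        pad = t * self.patch - L
        xp = np.pad(x[:, 0, :], ((0, 0), (0, pad))) if pad else x[:, 0, :]
        return xp.reshape(n, t, self.patch)

    def backward(self, g):
        n = g.shape[0]
        flat = g.reshape(n, -1)[:, : self._L]
        return flat[:, None, :]


class ToChannels(Layer):
    """(N, T, D) token matrix -> (N, D, T) channel layout for the conv stack."""

    def forward(self, x, train):
        return x.transpose(0, 2, 1)

    def backward(self, g):
        return g.transpose(0, 2, 1)


class Network:
    """A plain layer stack with joint forward/backward and parameter access."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self) -> tuple[list, list]:
        params = [p for layer in self.layers for p in layer.params]
        grads = [g for layer in self.layers for g in layer.grads]
        return params, grads

    def layer_inventory(self) -> list[str]:
        names = []
        for layer in self.layers:
            if isinstance(layer, TransformerEncoderLayer):
                names.append("TransformerEncoderLayer")
            else:
                names.append(type(layer).__name__)
        return names


class Adam:
    def __init__(self, params: list, grads: list, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
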