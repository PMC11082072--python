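"""Neural-network layers and the Adam optimizer for the encoder towers.

Layers are thin parameter containers exposing ``__call__`` on
:class:`~pepclr.autodiff.Tensor` inputs. Initialization is fully
determined by the numpy Generator passed in, so models built from the
same seed are parameter-identical.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np

from .autodiff import Tensor, concatenate, embedding_lookup, softmax

Array = np.ndarray

#: Large negative bias used to mask padded positions out of softmax/max.
NEG_INF = -1e9


def _sigmoid(x: Array) -> Array:
    return 1.0 / (1.0 + np.exp(-x))


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base: recursive parameter collection and train/eval mode."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def set_training(self, flag: bool) -> None:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.set_training(flag)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(flag)
        if hasattr(self, "training"):
            self.training = flag


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> Array:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int):
        self.weight = Parameter(_glorot(rng, in_dim, out_dim, (in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, rng: np.random.Generator, n_tokens: int, dim: int):
        self.weight = Parameter(rng.normal(0.0, 0.1, size=(n_tokens, dim)))

    def __call__(self, indices: Array) -> Tensor:
        return embedding_lookup(self.weight, indices)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gain + self.bias


class Dropout(Module):
    """Inverted dropout; a no-op in eval mode or at rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = rng
        self.training = False

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(keep)


class Conv1dSame(Module):
    """1-D convolution over the position axis with 'same' zero padding.

    Implemented as a sum of shifted matmuls: for kernel size K,
    y[:, t] = sum_k x_padded[:, t+k] @ W[k] + b. Input (B, L, C_in),
    output (B, L, C_out).
    """

    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int,
                 kernel_size: int):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.kernel_size = kernel_size
        fan_in = in_dim * kernel_size
        self.weights = [
            Parameter(_glorot(rng, fan_in, out_dim, (in_dim, out_dim)))
            for _ in range(kernel_size)
        ]
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        half = self.kernel_size // 2
        out: Optional[Tensor] = None
        for k, w in enumerate(self.weights):
            shift = k - half  # position offset into the input
            lo = max(0, shift)
            hi = min(L, L + shift)
            # rows of the output that receive this tap
            out_lo = lo - shift
            out_hi = hi - shift
            if lo >= hi:
                continue
            contrib = x[:, lo:hi, :] @ w
            if out_lo > 0 or out_hi < L:
                pads = []
                if out_lo > 0:
                    pads.append(Tensor(np.zeros((B, out_lo, w.shape[1]))))
                pads.append(contrib)
                if out_hi < L:
                    pads.append(Tensor(np.zeros((B, L - out_hi, w.shape[1]))))
                contrib = concatenate(pads, axis=1)
            out = contrib if out is None else out + contrib
        assert out is not None
        return out + self.bias


class LSTMLayer(Module):
    """Single-direction LSTM layer; returns per-timestep hidden states.

    The whole recurrence is one autodiff node with a hand-written
    backward-through-time pass: building the unrolled graph op by op
    costs ~20 tape nodes per timestep, which dominates runtime at
    peptide scale.
    """

    def __init__(self, rng: np.random.Generator, in_dim: int, hidden_dim: int):
        self.hidden_dim = hidden_dim
        s = 1.0 / math.sqrt(hidden_dim)
        self.w_ih = Parameter(rng.uniform(-s, s, size=(in_dim, 4 * hidden_dim)))
        self.w_hh = Parameter(rng.uniform(-s, s, size=(hidden_dim, 4 * hidden_dim)))
        bias = np.zeros(4 * hidden_dim)
        bias[hidden_dim : 2 * hidden_dim] = 1.0  # forget-gate bias
        self.bias = Parameter(bias)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        H = self.hidden_dim
        w_ih, w_hh, bias = self.w_ih, self.w_hh, self.bias
        xd = x.data
        xw = xd @ w_ih.data + bias.data  # (B, L, 4H)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        # caches for backward-through-time
        gates_cache = np.empty((L, B, 4 * H))
        c_cache = np.empty((L, B, H))
        h_prev_cache = np.empty((L, B, H))
        hs = np.empty((B, L, H))
        for t in range(L):
            h_prev_cache[t] = h
            a = xw[:, t, :] + h @ w_hh.data
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            gates_cache[t] = np.concatenate([i, f, g, o], axis=1)
            c_cache[t] = c
            hs[:, t, :] = h

        def back(grad_hs: np.ndarray):
            d_x = np.zeros_like(xd)
            d_wih = np.zeros_like(w_ih.data)
            d_whh = np.zeros_like(w_hh.data)
            d_bias = np.zeros_like(bias.data)
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in range(L - 1, -1, -1):
                i = gates_cache[t][:, :H]
                f = gates_cache[t][:, H : 2 * H]
                g = gates_cache[t][:, 2 * H : 3 * H]
                o = gates_cache[t][:, 3 * H :]
                c_t = c_cache[t]
                c_prev = c_cache[t - 1] if t > 0 else np.zeros((B, H))
                tc = np.tanh(c_t)
                dh = grad_hs[:, t, :] + dh_next
                do = dh * tc
                dc = dc_next + dh * o * (1.0 - tc ** 2)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                da = np.concatenate([
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g ** 2),
                    do * o * (1.0 - o),
                ], axis=1)
                d_x[:, t, :] = da @ w_ih.data.T
                d_wih += xd[:, t, :].T @ da
                d_whh += h_prev_cache[t].T @ da
                d_bias += da.sum(axis=0)
                dh_next = da @ w_hh.data.T
                dc_next = dc * f
            return ((x, d_x), (w_ih, d_wih), (w_hh, d_whh), (bias, d_bias))

        return Tensor(hs, _parents=(x, w_ih, w_hh, bias), _backward=back)


class MultiHeadSelfAttention(Module):
    """Standard scaled-dot-product self-attention with key padding mask.

    The post-softmax attention weights of the most recent forward pass
    are kept (as plain arrays) on ``last_attention`` for interpretation.
    """

    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int):
        if dim % n_heads != 0:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.wq = Linear(rng, dim, dim)
        self.wk = Linear(rng, dim, dim)
        self.wv = Linear(rng, dim, dim)
        self.wo = Linear(rng, dim, dim)
        self.last_attention: Optional[Array] = None

    def __call__(self, x: Tensor, mask: Array) -> Tensor:
        B, T, D = x.shape
        h, hd = self.n_heads, self.head_dim

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(B, T, h, hd).transpose((0, 2, 1, 3))

        q = split_heads(self.wq(x))
        k = split_heads(self.wk(x))
        v = split_heads(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(hd))
        # mask out padded keys: (B, 1, 1, T) additive bias
        bias = (1.0 - mask)[:, None, None, :] * NEG_INF
        attn = softmax(scores + Tensor(bias), axis=-1)
        self.last_attention = attn.data.copy()
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, T, D)
        return self.wo(out)


class TransformerBlock(Module):
    """Pre-norm transformer encoder block (attention + position-wise FFN)."""

    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int,
                 ffn_dim: int, dropout: Dropout):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(rng, dim, n_heads)
        self.ln2 = LayerNorm(dim)
        self.ffn1 = Linear(rng, dim, ffn_dim)
        self.ffn2 = Linear(rng, ffn_dim, dim)
        self.dropout = dropout

    def __call__(self, x: Tensor, mask: Array) -> Tensor:
        x = x + self.dropout(self.attn(self.ln1(x), mask))
        x = x + self.dropout(self.ffn2(self.ffn1(self.ln2(x)).relu()))
        return x


class Adam:
    """Adam optimizer (the paper-stated learning rate 1e-3 is the default)."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
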