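"""Neural-network building blocks on the autodiff engine.

Layers follow the common deep-learning conventions: uniform
``U(-1/sqrt(fan_in), 1/sqrt(fan_in))`` initialisation for affine and
recurrent weights, dual bias vectors per LSTM gate (input-side and
recurrent-side), and post-norm transformer encoder blocks.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "CausalConv1d",
    "LSTM",
    "LayerNorm",
    "MultiheadSelfAttention",
    "sinusoidal_positions",
]


class Module:
    """Base class: parameter registry plus state_dict round-tripping."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError("parameter shape mismatch")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


def _uniform(rng: np.random.Generator, shape, bound: float) -> Tensor:
    t = Tensor(rng.uniform(-bound, bound, size=shape))
    t.requires_grad = True
    return t


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_features)
        self.weight = _uniform(rng, (in_features, out_features), bound)
        self.bias = _uniform(rng, (out_features,), bound)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class CausalConv1d(Module):
    """Dilated causal 1-D convolution over (batch, time, channels) input.

    Implemented as a sum of delayed affine maps: output at position t sees
    inputs at t, t-d, ..., t-(K-1)d only, with zero left-padding.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_channels * kernel_size)
        self.weight = _uniform(rng, (kernel_size, in_channels, out_channels), bound)
        self.bias = _uniform(rng, (out_channels,), bound)
        self.kernel_size = kernel_size
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        b, length, _ = x.shape
        pad_len = self.dilation * (self.kernel_size - 1)
        pad = Tensor(np.zeros((b, pad_len, x.shape[2])))
        xp = concat([pad, x], axis=1)
        out = None
        for k in range(self.kernel_size):
            # tap k is delayed by (K-1-k)*d relative to the output position
            start = k * self.dilation
            term = xp[:, start:start + length, :] @ self.weight[k]
            out = term if out is None else out + term
        return out + self.bias


class LSTM(Module):
    """Single LSTM layer, dual-bias gate convention, gate order (i, f, g, o)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(hidden_size)
        self.w_ih = _uniform(rng, (input_size, 4 * hidden_size), bound)
        self.w_hh = _uniform(rng, (hidden_size, 4 * hidden_size), bound)
        self.b_ih = _uniform(rng, (4 * hidden_size,), bound)
        self.b_hh = _uniform(rng, (4 * hidden_size,), bound)
        self.hidden_size = hidden_size

    def forward(self, x: Tensor) -> Tensor:
        """Returns the hidden-state sequence, shape (batch, time, hidden).

        The whole recurrence is one autodiff node: the forward pass caches
        the gate activations and cell states, and the backward pass runs the
        standard backpropagation-through-time recursions in vectorized
        numpy.  This keeps the tape small and the per-batch cost dominated
        by the matrix products.
        """
        b, length, _ = x.shape
        n = self.hidden_size
        xd = x.data
        w_ih, w_hh = self.w_ih.data, self.w_hh.data
        bias = self.b_ih.data + self.b_hh.data
        xw = xd @ w_ih + bias                  # (b, L, 4n): input contraction
        hs = np.zeros((b, length + 1, n))      # hs[:, t] is h_{t-1}
        cs = np.zeros((b, length + 1, n))
        gates = np.zeros((b, length, 4 * n))   # cached i, f, g, o
        tanh_c = np.zeros((b, length, n))
        for t in range(length):
            z = xw[:, t, :] + hs[:, t, :] @ w_hh
            i = 1.0 / (1.0 + np.exp(-z[:, 0:n]))
            f = 1.0 / (1.0 + np.exp(-z[:, n:2 * n]))
            g = np.tanh(z[:, 2 * n:3 * n])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * n:]))
            c = f * cs[:, t, :] + i * g
            tc = np.tanh(c)
            cs[:, t + 1, :] = c
            hs[:, t + 1, :] = o * tc
            gates[:, t, 0:n] = i
            gates[:, t, n:2 * n] = f
            gates[:, t, 2 * n:3 * n] = g
            gates[:, t, 3 * n:] = o
            tanh_c[:, t, :] = tc

        parents = (x, self.w_ih, self.w_hh, self.b_ih, self.b_hh)

        def backward(grad_h, lay=self, x=x, xd=xd, hs=hs, cs=cs,
                     gates=gates, tanh_c=tanh_c):
            dz = np.zeros((b, length, 4 * n))
            dh_next = np.zeros((b, n))
            dc_next = np.zeros((b, n))
            w_hh_T = lay.w_hh.data.T
            for t in range(length - 1, -1, -1):
                i = gates[:, t, 0:n]
                f = gates[:, t, n:2 * n]
                g = gates[:, t, 2 * n:3 * n]
                o = gates[:, t, 3 * n:]
                tc = tanh_c[:, t, :]
                dh = grad_h[:, t, :] + dh_next
                dc = dh * o * (1.0 - tc * tc) + dc_next
                dzt = dz[:, t, :]
                dzt[:, 0:n] = dc * g * i * (1.0 - i)
                dzt[:, n:2 * n] = dc * cs[:, t, :] * f * (1.0 - f)
                dzt[:, 2 * n:3 * n] = dc * i * (1.0 - g * g)
                dzt[:, 3 * n:] = dh * tc * o * (1.0 - o)
                dh_next = dzt @ w_hh_T
                dc_next = dc * f
            if x.requires_grad:
                x._accum(dz @ lay.w_ih.data.T)
            db = dz.sum(axis=(0, 1))
            dz_flat = dz.reshape(-1, 4 * n)
            lay.w_ih._accum(xd.reshape(-1, xd.shape[2]).T @ dz_flat)
            lay.w_hh._accum(hs[:, :-1, :].reshape(-1, n).T @ dz_flat)
            lay.b_ih._accum(db)
            lay.b_hh._accum(db.copy())

        return Tensor._make(hs[:, 1:, :], parents, backward)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(dim))
        self.gain.requires_grad = True
        self.bias = Tensor(np.zeros(dim))
        self.bias.requires_grad = True
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gain + self.bias


class MultiheadSelfAttention(Module):
    """Multi-head self-attention with fused QKV projection and output projection."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must divide by n_heads")
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)
        self.n_heads = n_heads
        self.dim = dim

    def forward(self, x: Tensor) -> Tensor:
        b, length, d = x.shape
        hd = d // self.n_heads
        qkv = self.qkv(x)  # (b, L, 3d)
        q = qkv[:, :, 0:d].reshape(b, length, self.n_heads, hd).transpose(0, 2, 1, 3)
        k = qkv[:, :, d:2 * d].reshape(b, length, self.n_heads, hd).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * d:3 * d].reshape(b, length, self.n_heads, hd).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, length, d)
        return self.out(ctx)


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    """Parameter-free sinusoidal positional encoding, shape (length, dim)."""
    pos = np.arange(length)[:, None]
    i = np.arange(dim // 2)[None, :]
    angles = pos / np.power(10000.0, 2.0 * i / dim)
    enc = np.zeros((length, dim))
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles)
    return enc
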