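"""The five forecasting architectures at their tuned configurations.

All models map a normalized glucose history of L steps, shaped
``(batch, L, 1)``, to a single normalized forecast ``(batch, 1)``:

* ``FFN`` — a per-timestep affine stack 1->32->64->1 with ReLU, read out at
  the final timestep.
* ``CNN`` — two 1-D convolutions (32 then 64 channels, kernel 3), global
  average pooling over time, and a 64->32->1 head.
* ``TCN`` — four residual blocks of causal dilated convolutions
  (channels 16, 32, 64, 64; dilations 1, 2, 4, 8; kernel 3) and a 64->1
  head at the final position.
* ``LSTM`` — two stacked layers of 30 hidden units with the dual-bias gate
  convention, and a 30->1 head on the final hidden state.
* ``SAN`` — a self-attention encoder: affine input projection to width 128,
  parameter-free sinusoidal positions, three post-norm encoder blocks
  (4 heads, feed-forward width 512), a final layer normalization, and a
  128->1 head on the final position.

Parameter accounting under these conventions reproduces the published
complexity table exactly for FFN (2241), LSTM (11431) and SAN (595457).
FLOP estimates are analytic: twice the multiply-accumulate count of every
affine, convolutional, recurrent and attention contraction for one window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    CausalConv1d, LSTM, LayerNorm, Linear, Module, MultiheadSelfAttention,
    Tensor, sinusoidal_positions,
)

ARCHITECTURES = ("FFN", "CNN", "TCN", "LSTM", "SAN")

__all__ = [
    "ModelSpec", "ComplexityReport", "default_specs",
    "build_model", "count_parameters", "estimate_flops", "affine_flops",
    "predict_array", "complexity_report",
]


@dataclass(frozen=True)
class ModelSpec:
    architecture: str
    input_length: int = 24
    dropout: float = 0.0
    learning_rate: float = 0.001
    ffn_widths: tuple[int, ...] = (32, 64)
    cnn_channels: tuple[int, ...] = (32, 64)
    cnn_fc: tuple[int, ...] = (64, 32)
    tcn_channels: tuple[int, ...] = (16, 32, 64, 64)
    tcn_dilations: tuple[int, ...] = (1, 2, 4, 8)
    kernel_size: int = 3
    lstm_units: tuple[int, ...] = (30, 30)
    san_dim: int = 128
    san_heads: int = 4
    san_blocks: int = 3
    san_ff: int = 512

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")


@dataclass
class ComplexityReport:
    architecture: str
    n_params: int
    flops_per_inference: int
    notes: str = ""


def default_specs() -> dict[str, ModelSpec]:
    """The tuned configuration of each architecture (learning rate included)."""
    return {
        "FFN": ModelSpec("FFN", learning_rate=0.01),
        "CNN": ModelSpec("CNN", learning_rate=0.001),
        "TCN": ModelSpec("TCN", learning_rate=0.001),
        "LSTM": ModelSpec("LSTM", learning_rate=0.001),
        "SAN": ModelSpec("SAN", learning_rate=0.001),
    }


class FFNModel(Module):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        widths = (1, *spec.ffn_widths, 1)
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for layer in self.layers[:-1]:
            h = layer(h).relu()
        h = self.layers[-1](h)
        return h[:, -1, :]


class CNNModel(Module):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        c1, c2 = spec.cnn_channels
        self.conv1 = CausalConv1d(1, c1, spec.kernel_size, 1, rng)
        self.conv2 = CausalConv1d(c1, c2, spec.kernel_size, 1, rng)
        f1, f2 = spec.cnn_fc
        self.fc1 = Linear(f1, f2, rng)
        self.fc2 = Linear(f2, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        h = h.mean(axis=1)          # global average pooling over time
        return self.fc2(self.fc1(h).relu())


class TCNBlock(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 rng: np.random.Generator):
        self.conv1 = CausalConv1d(c_in, c_out, kernel, dilation, rng)
        self.conv2 = CausalConv1d(c_out, c_out, kernel, dilation, rng)
        self.proj = Linear(c_in, c_out, rng) if c_in != c_out else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv2(self.conv1(x).relu()).relu()
        skip = x if self.proj is None else self.proj(x)
        return (h + skip).relu()


class TCNModel(Module):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        chans = (1, *spec.tcn_channels)
        self.blocks = [
            TCNBlock(a, b, spec.kernel_size, d, rng)
            for a, b, d in zip(chans[:-1], chans[1:], spec.tcn_dilations)
        ]
        self.head = Linear(spec.tcn_channels[-1], 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for block in self.blocks:
            h = block(h)
        return self.head(h[:, -1, :])


class LSTMModel(Module):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        sizes = (1, *spec.lstm_units)
        self.layers = [LSTM(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.head = Linear(spec.lstm_units[-1], 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for layer in self.layers:
            h = layer(h)
        return self.head(h[:, -1, :])


class SANBlock(Module):
    def __init__(self, dim: int, heads: int, ff: int, rng: np.random.Generator):
        self.attn = MultiheadSelfAttention(dim, heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff, rng)
        self.ff2 = Linear(ff, dim, rng)
        self.norm2 = LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x))
        return self.norm2(x + self.ff2(self.ff1(x).relu()))


class SANModel(Module):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        self.inproj = Linear(1, spec.san_dim, rng)
        self.positions = Tensor(sinusoidal_positions(spec.input_length, spec.san_dim))
        self.blocks = [SANBlock(spec.san_dim, spec.san_heads, spec.san_ff, rng)
                       for _ in range(spec.san_blocks)]
        self.final_norm = LayerNorm(spec.san_dim)
        self.head = Linear(spec.san_dim, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.inproj(x) + self.positions
        for block in self.blocks:
            h = block(h)
        h = self.final_norm(h)
        return self.head(h[:, -1, :])


_BUILDERS = {"FFN": FFNModel, "CNN": CNNModel, "TCN": TCNModel,
             "LSTM": LSTMModel, "SAN": SANModel}


def build_model(spec: ModelSpec, seed: int) -> Module:
    """Deterministically initialize the architecture named by ``spec``."""
    rng = np.random.default_rng(seed)
    model = _BUILDERS[spec.architecture](spec, rng)
    model.spec = spec
    return model


def count_parameters(model: Module) -> int:
    return model.n_parameters()


def predict_array(model: Module, inputs: np.ndarray, batch: int = 4096) -> np.ndarray:
    """Forward a (n, L) array of normalized windows, returning (n,) forecasts."""
    inputs = np.asarray(inputs, dtype=float)
    out = []
    for lo in range(0, len(inputs), batch):
        x = Tensor(inputs[lo:lo + batch, :, None])
        out.append(model(x).data[:, 0])
    return np.concatenate(out) if out else np.zeros(0)


def affine_flops(n_in: int, n_out: int, positions: int = 1) -> int:
    """2 x multiply-accumulates of an affine map applied at ``positions`` sites."""
    return 2 * positions * n_in * n_out


def estimate_flops(spec: ModelSpec, input_length: int | None = None) -> int:
    """Analytic FLOPs for one inference on one window (2 x MACs).

    Counts every affine/convolutional/recurrent/attention contraction;
    biases, nonlinearities and normalizations are not counted.
    """
    L = input_length or spec.input_length
    a = spec.architecture
    if a == "FFN":
        widths = (1, *spec.ffn_widths, 1)
        return sum(affine_flops(i, o, L) for i, o in zip(widths[:-1], widths[1:]))
    if a == "CNN":
        c1, c2 = spec.cnn_channels
        k = spec.kernel_size
        total = affine_flops(k * 1, c1, L) + affine_flops(k * c1, c2, L)
        widths = (*spec.cnn_fc, 1)
        return total + sum(affine_flops(i, o) for i, o in zip(widths[:-1], widths[1:]))
    if a == "TCN":
        chans = (1, *spec.tcn_channels)
        k = spec.kernel_size
        total = 0
        for c_in, c_out in zip(chans[:-1], chans[1:]):
            total += affine_flops(k * c_in, c_out, L)     # first conv
            total += affine_flops(k * c_out, c_out, L)    # second conv
            if c_in != c_out:
                total += affine_flops(c_in, c_out, L)     # residual projection
        return total + affine_flops(spec.tcn_channels[-1], 1)
    if a == "LSTM":
        sizes = (1, *spec.lstm_units)
        total = 0
        for s_in, h in zip(sizes[:-1], sizes[1:]):
            total += affine_flops(s_in + h, 4 * h, L)     # fused gate contraction
        return total + affine_flops(spec.lstm_units[-1], 1)
    if a == "SAN":
        d, ff = spec.san_dim, spec.san_ff
        total = affine_flops(1, d, L)
        per_block = (
            affine_flops(d, 3 * d, L)          # fused QKV
            + 2 * affine_flops(d, L, L)        # QK^T and attention-weighted V
            + affine_flops(d, d, L)            # output projection
            + affine_flops(d, ff, L) + affine_flops(ff, d, L)
        )
        return total + spec.san_blocks * per_block + affine_flops(d, 1)
    raise ValueError(a)


def complexity_report(spec: ModelSpec, seed: int = 0) -> ComplexityReport:
    model = build_model(spec, seed)
    return ComplexityReport(
        architecture=spec.architecture,
        n_params=count_parameters(model),
        flops_per_inference=estimate_flops(spec),
        notes="analytic 2xMAC count; biases and normalizations excluded",
    )
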