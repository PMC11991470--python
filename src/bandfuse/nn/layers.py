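"""Neural-network layers built on the autograd primitives.

Initialization follows He (fan-in) for convolutions and ReLU linears and
Glorot for attention projections; every layer takes an explicit
``np.random.Generator`` so weight draws are reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import (Tensor, adaptive_avg_pool_hw, concat, conv2d, conv3d,
                     depthwise_conv2d, maxpool_hw, softmax)

__all__ = ["Module", "Sequential", "Linear", "Conv2d", "DepthwiseConv2d",
           "Conv3d", "BatchNorm", "LayerNorm", "MaxPool2d", "ReLU", "Tanh",
           "GlobalAvgPool2d", "AdaptiveAvgPool2d", "Flatten",
           "MultiHeadSelfAttention", "TransformerEncoderLayer",
           "sinusoidal_positional_encoding"]


class Module:
    """Minimal module: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def __call__(self, x):
        return self.forward(x)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield f"{prefix}{name}", value
        for cname, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{cname}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def train(self) -> "Module":
        self.training = True
        for _, child in self._children():
            child.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for _, child in self._children():
            child.eval()
        return self

    # state includes non-trainable buffers (batch-norm running stats)
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters(prefix)}
        for cname, child in self._children():
            for key, val in child.state_dict(f"{prefix}{cname}.").items():
                state.setdefault(key, val)
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                state[f"{prefix}{name}"] = value.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, p in self.named_parameters(prefix):
            p.data = state[name].astype(np.float32).copy()
        for name, value in list(vars(self).items()):
            if isinstance(value, np.ndarray) and f"{prefix}{name}" in state:
                setattr(self, name, state[f"{prefix}{name}"].copy())
        for cname, child in self._children():
            child.load_state_dict(state, f"{prefix}{cname}.")


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Tanh(Module):
    def forward(self, x):
        return x.tanh()


class Flatten(Module):
    def forward(self, x):
        return x.reshape(x.shape[0], -1)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, gain: str = "relu"):
        super().__init__()
        if gain == "relu":
            std = math.sqrt(2.0 / in_features)
            w = rng.normal(0.0, std, size=(out_features, in_features))
        else:  # glorot-uniform
            bound = math.sqrt(6.0 / (in_features + out_features))
            w = rng.uniform(-bound, bound, size=(out_features, in_features))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x):
        return x @ self.weight.swapaxes(-1, -2) + self.bias


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(
            rng.normal(0.0, math.sqrt(2.0 / fan_in),
                       size=(out_ch, in_ch, kernel, kernel)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        fan_in = kernel * kernel
        self.weight = Tensor(
            rng.normal(0.0, math.sqrt(2.0 / fan_in),
                       size=(channels, kernel, kernel)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(channels), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return depthwise_conv2d(x, self.weight, self.bias, self.stride,
                                self.padding)


class Conv3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, padding: int = 1, bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel ** 3
        self.weight = Tensor(
            rng.normal(0.0, math.sqrt(2.0 / fan_in),
                       size=(out_ch, in_ch, kernel, kernel, kernel)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.padding = padding

    def forward(self, x):
        return conv3d(x, self.weight, self.bias, self.padding)


class BatchNorm(Module):
    """Batch normalization over all axes except the channel axis (axis 1).

    Works for 4-D (2-D convs) and 5-D (3-D convs) activations.  Training
    mode normalizes with batch statistics and updates exponential running
    estimates; eval mode uses the running estimates.  With ``momentum``
    set to ``None`` the running estimates become cumulative averages —
    used to recalibrate statistics against the final weights after a
    short training run, where the exponential estimates lag the fast-
    moving activations.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps, self.momentum = eps, momentum
        self._n_batches = 0

    def reset_running(self) -> None:
        self.running_mean[:] = 0.0
        self.running_var[:] = 1.0
        self._n_batches = 0

    def forward(self, x):
        axes = tuple(a for a in range(x.ndim) if a != 1)
        shape = [1] * x.ndim
        shape[1] = -1
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            if self.momentum is None:
                n = self._n_batches
                self.running_mean = ((n * self.running_mean
                                      + mu.data.reshape(-1)) / (n + 1))
                self.running_var = ((n * self.running_var
                                     + var.data.reshape(-1)) / (n + 1))
                self._n_batches = n + 1
            else:
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * mu.data.reshape(-1))
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * var.data.reshape(-1))
            xhat = xc * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean.reshape(shape)
            sd = np.sqrt(self.running_var.reshape(shape) + self.eps)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


class MaxPool2d(Module):
    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def forward(self, x):
        return maxpool_hw(x, self.k)


class GlobalAvgPool2d(Module):
    def forward(self, x):
        return x.mean(axis=(2, 3))


class AdaptiveAvgPool2d(Module):
    def __init__(self, out_hw: tuple[int, int]):
        super().__init__()
        self.out_hw = out_hw

    def forward(self, x):
        return adaptive_avg_pool_hw(x, self.out_hw)


def sinusoidal_positional_encoding(n_positions: int, d_model: int) -> np.ndarray:
    """Standard sine/cosine positional encodings.

    ``PE[pos, 2i] = sin(pos / 10000^(2i/d)); PE[pos, 2i+1] = cos(...)``.
    """
    if d_model % 2:
        raise ValueError("d_model must be even")
    pos = np.arange(n_positions)[:, None].astype(np.float64)
    i = np.arange(0, d_model, 2)[None, :].astype(np.float64)
    angle = pos / np.power(10000.0, i / d_model)
    pe = np.zeros((n_positions, d_model), dtype=np.float32)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention, softmax(QKᵀ/√d_k)V per head.

    The last forward's attention weights are kept (as a plain array) in
    ``last_attn`` with shape (batch, heads, tokens, tokens) for
    inspection; each row sums to 1 by construction.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.qkv = Linear(d_model, 3 * d_model, rng, gain="glorot")
        self.out = Linear(d_model, d_model, rng, gain="glorot")
        self.last_attn: np.ndarray | None = None

    def forward(self, x):
        N, T, D = x.shape
        qkv = self.qkv(x).reshape(N, T, 3, self.n_heads, self.d_k)
        qkv = qkv.transpose(2, 0, 3, 1, 4)          # (3, N, h, T, d_k)
        q = qkv.reshape(3, N, self.n_heads, T, self.d_k)
        # slice out q/k/v without a gather op: multiply by basis and sum axis 0
        # simpler: three separate projections via views of the data
        scores_parent = q
        q_t = _take_first_axis(scores_parent, 0)
        k_t = _take_first_axis(scores_parent, 1)
        v_t = _take_first_axis(scores_parent, 2)
        scores = q_t @ k_t.swapaxes(-1, -2) * (1.0 / math.sqrt(self.d_k))
        attn = softmax(scores, axis=-1)
        self.last_attn = attn.data.copy()
        ctx = attn @ v_t                            # (N, h, T, d_k)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(N, T, D)
        return self.out(ctx)


def _take_first_axis(x: Tensor, index: int) -> Tensor:
    """Differentiable selection of one slice along axis 0."""
    out_data = x.data[index]

    def backward(g):
        if x.requires_grad:
            grad = np.zeros_like(x.data)
            grad[index] = g
            x._accum(grad)

    return Tensor._from_op(out_data, (x,), backward)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: MHSA and position-wise FFN, each wrapped
    in a residual connection followed by layer normalization.  The FFN is
    ``max(0, X W1 + b1) W2 + b2``.
    """

    def __init__(self, d_model: int, n_heads: int, ffn_width: int,
                 rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.ffn1 = Linear(d_model, ffn_width, rng)
        self.ffn2 = Linear(ffn_width, d_model, rng, gain="glorot")
        self.norm2 = LayerNorm(d_model)

    def forward(self, x):
        x = self.norm1(x + self.attn(x))
        return self.norm2(x + self.ffn2(self.ffn1(x).relu()))
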