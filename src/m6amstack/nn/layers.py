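"""Layer building blocks on top of the autodiff engine.

All layers take and return tensors laid out as (batch, length, channels);
heads collapse to (batch,) probabilities.  Weight initialization is Glorot
uniform, drawn from a generator passed in at construction so a seed fully
determines the parameters.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .recurrent import gru_forward, lstm_forward

__all__ = [
    "Module", "Linear", "Conv1D", "SEBlock", "DenseBlock",
    "BiLSTM", "BiGRU", "Dropout",
]

DTYPE = np.float32


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Module:
    """Base class: parameter discovery by attribute walk."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Tensor], seen: set[int]) -> None:
        for value in vars(self).values():
            self._collect_value(value, params, seen)

    def _collect_value(self, value, params, seen) -> None:
        if isinstance(value, Tensor) and value.requires_grad:
            if id(value) not in seen:
                seen.add(id(value))
                params.append(value)
        elif isinstance(value, Module):
            value._collect(params, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                self._collect_value(v, params, seen)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for value in vars(self).values():
            self._set_training_value(value, flag)

    def _set_training_value(self, value, flag) -> None:
        if isinstance(value, Module):
            value.set_training(flag)
        elif isinstance(value, (list, tuple)):
            for v in value:
                self._set_training_value(v, flag)

    # -- serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        self._walk_named(out, "")
        return out

    def _walk_named(self, out: dict, prefix: str) -> None:
        for name, value in vars(self).items():
            self._walk_value(value, out, f"{prefix}{name}")

    def _walk_value(self, value, out, key) -> None:
        if isinstance(value, Tensor) and value.requires_grad:
            out[key] = value.data
        elif isinstance(value, Module):
            value._walk_named(out, key + ".")
        elif isinstance(value, (list, tuple)):
            for i, v in enumerate(value):
                self._walk_value(v, out, f"{key}.{i}")

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {}
        self._walk_tensors(own, "")
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch on keys: {sorted(missing)}")
        for key, tensor in own.items():
            if tensor.data.shape != state[key].shape:
                raise ValueError(f"shape mismatch for {key}")
            tensor.data = state[key].astype(DTYPE)

    def _walk_tensors(self, out: dict, prefix: str) -> None:
        for name, value in vars(self).items():
            self._walk_tensor_value(value, out, f"{prefix}{name}")

    def _walk_tensor_value(self, value, out, key) -> None:
        if isinstance(value, Tensor) and value.requires_grad:
            out[key] = value
        elif isinstance(value, Module):
            value._walk_tensors(out, key + ".")
        elif isinstance(value, (list, tuple)):
            for i, v in enumerate(value):
                self._walk_tensor_value(v, out, f"{key}.{i}")


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.w = Tensor(_glorot(rng, (in_dim, out_dim), in_dim, out_dim),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_dim, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1D(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, dilation: int = 1,
                 padding: str = "same"):
        fan_in = kernel * in_ch
        self.w = Tensor(_glorot(rng, (kernel, in_ch, out_ch), fan_in, out_ch),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True)
        self.dilation = dilation
        self.padding = padding
        self.kernel = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv1d(x, self.w, self.b, dilation=self.dilation,
                         padding=self.padding)


class SEBlock(Module):
    """Squeeze-and-excitation channel gate in residual form.

    Squeeze: per-channel global average over positions.  Excite: bottleneck
    linear -> ReLU -> restore linear -> sigmoid, giving gates in (0, 1).
    Output is ``x + gate * x`` — the input is added back so gating never
    destroys the original feature map.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.channels = channels

    def gates(self, x: Tensor) -> Tensor:
        squeezed = ag.global_avg_pool(x)            # (B, C)
        return self.fc2(self.fc1(squeezed).relu()).sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        g = self.gates(x)
        B, C = g.shape
        return x + x * g.reshape(B, 1, C)


class DenseBlock(Module):
    """Densely connected stack of Conv1D+ELU layers.

    Layer i consumes the channel-concatenation of the block input and all
    previous layer outputs, so a block of X layers realizes X(X+1)/2
    input-to-layer connections.  ``connection_count()`` reports the count
    observed during the last forward pass.
    """

    def __init__(self, in_ch: int, n_layers: int, growth: int, kernel: int,
                 rng: np.random.Generator):
        self.layers = [
            Conv1D(in_ch + i * growth, growth, kernel, rng)
            for i in range(n_layers)
        ]
        self.n_layers = n_layers
        self.growth = growth
        self.out_ch = in_ch + n_layers * growth
        self._last_connection_count = 0

    def __call__(self, x: Tensor) -> Tensor:
        feats = [x]
        connections = 0
        for layer in self.layers:
            connections += len(feats)  # one edge per consumed feature map
            inp = ag.concat(feats, axis=-1) if len(feats) > 1 else feats[0]
            feats.append(layer(inp).elu())
        self._last_connection_count = connections
        return ag.concat(feats, axis=-1)

    def connection_count(self) -> int:
        return self._last_connection_count


class _RecurrentBase(Module):
    n_gates = 4
    _forward = staticmethod(lstm_forward)

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        G = self.n_gates
        self.wx_f = Tensor(_glorot(rng, (in_dim, G * hidden), in_dim, hidden),
                           requires_grad=True)
        self.wh_f = Tensor(_glorot(rng, (hidden, G * hidden), hidden, hidden),
                           requires_grad=True)
        self.b_f = Tensor(np.zeros(G * hidden, dtype=DTYPE), requires_grad=True)
        self.wx_b = Tensor(_glorot(rng, (in_dim, G * hidden), in_dim, hidden),
                           requires_grad=True)
        self.wh_b = Tensor(_glorot(rng, (hidden, G * hidden), hidden, hidden),
                           requires_grad=True)
        self.b_b = Tensor(np.zeros(G * hidden, dtype=DTYPE), requires_grad=True)
        self.hidden = hidden

    def __call__(self, x: Tensor) -> Tensor:
        fwd = self._forward(x, self.wx_f, self.wh_f, self.b_f)
        rev_in = _reverse_time(x)
        bwd = _reverse_time(self._forward(rev_in, self.wx_b, self.wh_b, self.b_b))
        return ag.concat([fwd, bwd], axis=-1)  # (B, T, 2H)


def _reverse_time(x: Tensor) -> Tensor:
    out = Tensor(x.data[:, ::-1, :].copy(), x.requires_grad, (x,))

    def _backward(g):
        if x.requires_grad:
            x._accumulate(g[:, ::-1, :])

    out._backward = _backward
    return out


class BiLSTM(_RecurrentBase):
    n_gates = 4
    _forward = staticmethod(lstm_forward)


class BiGRU(_RecurrentBase):
    n_gates = 3
    _forward = staticmethod(gru_forward)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        return ag.dropout(x, self.rate, self.rng, self.training)
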