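"""The three base classifiers: dense-connectivity CNN with squeeze-and-
excitation attention, dilated CNN + BiLSTM, and a multi-scale residual CNN
+ BiGRU.  Each maps a batch of (L, 4) one-hot matrices to probabilities.

Structural constants follow the published design: 6 dense blocks each
followed by a residual SE gate (plus one SE gate on the input); 3 parallel
dilated branches with rates 1, 2, 3 feeding a BiLSTM; 6 cascaded
multi-scale residual blocks of 3 convolutional layers with 64 kernels each,
fused by a 192-filter convolution before a BiGRU.  Everything else
(kernel sizes, widths, training protocol) is unpublished and therefore an
explicit, overridable hyperparameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import (BiGRU, BiLSTM, Conv1D, DenseBlock, Dropout, Linear,
                        Module, SEBlock)
from .nn.optim import Adam

__all__ = [
    "ARCHITECTURES", "BaseModelSpec", "TrainConfig", "TrainedBaseModel",
    "ConfigurationError", "DivergenceError",
    "build_model", "train_base_model", "predict_proba",
    "save_trained_model", "load_trained_model",
    "DenseNetSENet", "DCNNBiLSTM", "MSRNBiGRU",
]


class ConfigurationError(ValueError):
    pass


class DivergenceError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 3e-3
    optimizer_name: str = "adam"
    early_stopping_patience: int = 5
    dropout_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("epochs", "batch_size", "early_stopping_patience"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")


_DEFAULT_HP = {
    "densenet_senet": dict(n_blocks=6, layers_per_block=2, growth=8, kernel=3,
                           se_reduction=2, transition_compression=0.5,
                           head_units=32),
    "dcnn_bilstm": dict(filters=16, kernel=3, dilations=(1, 2, 3), pool=2,
                        lstm_units=16),
    "msrn_bigru": dict(n_blocks=6, block_channels=64, kernel_sizes=(3, 5),
                       fusion_filters=192, fusion_kernel=1, pool=2,
                       gru_units=16),
}


@dataclass
class BaseModelSpec:
    architecture: str
    hyperparameters: dict = field(default_factory=dict)
    input_shape: tuple[int, int] = (41, 4)

    def __post_init__(self):
        if self.architecture not in _DEFAULT_HP:
            raise ConfigurationError(
                f"unknown architecture {self.architecture!r}; "
                f"choose from {sorted(_DEFAULT_HP)}")
        hp = dict(_DEFAULT_HP[self.architecture])
        unknown = set(self.hyperparameters) - set(hp)
        if unknown:
            raise ConfigurationError(
                f"unknown hyperparameters for {self.architecture}: "
                f"{sorted(unknown)}")
        hp.update(self.hyperparameters)
        self.hyperparameters = hp
        self.input_shape = tuple(self.input_shape)


# ---------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------

class DenseNetSENet(Module):
    """SE gate on the raw input, then 6 dense blocks each followed by a
    residual SE gate, with 1x1 transition convolutions controlling channel
    growth, global average pooling and a small dense head."""

    def __init__(self, input_shape, hp, rng, dropout_rate=0.3):
        L, C = input_shape
        self.input_se = SEBlock(C, hp["se_reduction"], rng)
        self.dense_blocks: list[DenseBlock] = []
        self.se_blocks: list[SEBlock] = []
        self.transitions: list[Conv1D] = []
        ch = C
        for b in range(hp["n_blocks"]):
            block = DenseBlock(ch, hp["layers_per_block"], hp["growth"],
                               hp["kernel"], rng)
            ch = block.out_ch
            self.dense_blocks.append(block)
            self.se_blocks.append(SEBlock(ch, hp["se_reduction"], rng))
            if b < hp["n_blocks"] - 1:
                out = max(4, int(ch * hp["transition_compression"]))
                self.transitions.append(Conv1D(ch, out, 1, rng))
                ch = out
        self.head1 = Linear(ch, hp["head_units"], rng)
        self.drop = Dropout(dropout_rate, rng)
        self.head2 = Linear(hp["head_units"], 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.input_se(x)
        for i, block in enumerate(self.dense_blocks):
            h = self.se_blocks[i](block(h))
            if i < len(self.transitions):
                h = self.transitions[i](h).elu()
        h = ag.global_avg_pool(h)
        h = self.drop(self.head1(h).relu())
        B = h.shape[0]
        return self.head2(h).sigmoid().reshape(B)


class _DilatedBranch(Module):
    """One dilated block: conv, conv+ReLU, max-pool, dropout."""

    def __init__(self, in_ch, filters, kernel, dilation, pool, rng, dropout_rate):
        self.conv1 = Conv1D(in_ch, filters, kernel, rng, dilation=dilation)
        self.conv2 = Conv1D(filters, filters, kernel, rng, dilation=dilation)
        self.pool = pool
        self.drop = Dropout(dropout_rate, rng)
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(x)
        h = self.conv2(h).relu()
        h = ag.max_pool1d(h, self.pool)
        return self.drop(h)


class DCNNBiLSTM(Module):
    """Three parallel dilated-convolution branches (rates 1, 2, 3), their
    feature maps spliced channel-wise, then a BiLSTM and sigmoid head."""

    def __init__(self, input_shape, hp, rng, dropout_rate=0.3):
        L, C = input_shape
        self.branches = [
            _DilatedBranch(C, hp["filters"], hp["kernel"], rate, hp["pool"],
                           rng, dropout_rate)
            for rate in hp["dilations"]
        ]
        width = hp["filters"] * len(hp["dilations"])
        self.bilstm = BiLSTM(width, hp["lstm_units"], rng)
        self.head = Linear(2 * hp["lstm_units"], 1, rng)

    @property
    def dilation_rates(self) -> tuple[int, ...]:
        return tuple(b.dilation for b in self.branches)

    def __call__(self, x: Tensor) -> Tensor:
        h = ag.concat([branch(x) for branch in self.branches], axis=-1)
        h = self.bilstm(h)
        h = h.mean_axis(1)
        B = h.shape[0]
        return self.head(h).sigmoid().reshape(B)


class MSRB(Module):
    """Multi-scale residual block: two multi-scale convolutional layers
    (parallel kernels at the configured sizes, ReLU) and a 1x1 fusion
    convolution, each carrying `channels` kernels in total, plus a residual
    pass-through (1x1-projected when channel counts differ)."""

    def __init__(self, in_ch, channels, kernel_sizes, rng):
        per_scale = channels // len(kernel_sizes)
        self.scale1 = [Conv1D(in_ch, per_scale, k, rng) for k in kernel_sizes]
        self.scale2 = [Conv1D(channels, per_scale, k, rng) for k in kernel_sizes]
        self.fuse = Conv1D(channels, channels, 1, rng)
        self.fuse.w.data[:] = 0.0  # residual branch starts at zero so the
        self.project = Conv1D(in_ch, channels, 1, rng) if in_ch != channels else None
        # cascade begins near identity; without this the 6-block stack
        # saturates the downstream recurrent gates and never learns
        self.channels = channels

    @property
    def conv_layers(self) -> int:
        return 3  # scale1, scale2, fuse

    def __call__(self, x: Tensor) -> Tensor:
        h = ag.concat([c(x) for c in self.scale1], axis=-1).relu()
        h = ag.concat([c(h) for c in self.scale2], axis=-1).relu()
        h = self.fuse(h)
        res = self.project(x) if self.project is not None else x
        return (h + res).relu()


class MSRNBiGRU(Module):
    """Six cascaded multi-scale residual blocks whose outputs are fused
    hierarchically, a 192-filter convolution with average pooling, then a
    BiGRU and sigmoid head."""

    def __init__(self, input_shape, hp, rng, dropout_rate=0.3):
        L, C = input_shape
        self.blocks: list[MSRB] = []
        ch = C
        for _ in range(hp["n_blocks"]):
            block = MSRB(ch, hp["block_channels"], hp["kernel_sizes"], rng)
            self.blocks.append(block)
            ch = block.channels
        self.fusion = Conv1D(hp["block_channels"] * hp["n_blocks"],
                             hp["fusion_filters"], hp["fusion_kernel"], rng)
        self.pool = hp["pool"]
        self.bigru = BiGRU(hp["fusion_filters"], hp["gru_units"], rng)
        self.drop = Dropout(dropout_rate, rng)
        self.head = Linear(2 * hp["gru_units"], 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        outputs = []
        h = x
        for block in self.blocks:
            h = block(h)
            outputs.append(h)
        fused = self.fusion(ag.concat(outputs, axis=-1))
        fused = ag.avg_pool1d(fused, self.pool)
        h = self.bigru(fused)
        h = self.drop(h.mean_axis(1))
        B = h.shape[0]
        return self.head(h).sigmoid().reshape(B)


ARCHITECTURES = {
    "densenet_senet": DenseNetSENet,
    "dcnn_bilstm": DCNNBiLSTM,
    "msrn_bigru": MSRNBiGRU,
}


def build_model(spec: BaseModelSpec, seed: int = 0,
                dropout_rate: float = 0.3) -> Module:
    """Instantiate an untrained model; the seed fixes every initial weight."""
    cls = ARCHITECTURES[spec.architecture]
    rng = np.random.default_rng(seed)
    model = cls(spec.input_shape, spec.hyperparameters, rng,
                dropout_rate=dropout_rate)
    model._spec = spec
    return model


# ---------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------

@dataclass
class TrainedBaseModel:
    spec: BaseModelSpec
    model: Module
    training_meta: dict


def _bce(prob: Tensor, y: np.ndarray) -> Tensor:
    eps = 1e-7
    p = prob * (1.0 - 2 * eps) + eps  # keep logs finite
    yt = Tensor(y.astype(p.data.dtype))
    loss = -(yt * p.log() + (1.0 - yt) * (1.0 - p).log())
    return loss.mean()


def train_base_model(model: Module, X: np.ndarray, y: np.ndarray,
                     config: TrainConfig) -> TrainedBaseModel:
    """Minibatch Adam on binary cross-entropy, deterministic given the seed.

    Early stopping monitors the epoch-mean training loss with the configured
    patience (no validation split — callers wanting one hold data out
    themselves, as the cross-validation harness does).
    """
    X = np.ascontiguousarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if len(X) != len(y):
        raise ValueError(f"|X|={len(X)} != |y|={len(y)}")
    if len(X) < 2 or len(np.unique(y)) < 2:
        raise ValueError("training requires >= 2 samples with both classes")

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    model.set_training(True)

    n = len(X)
    best_loss = np.inf
    stall = 0
    epochs_run = 0
    final_loss = np.inf
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            model.zero_grad()
            prob = model(Tensor(X[idx]))
            loss = _bce(prob, y[idx])
            if not np.isfinite(loss.data):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}: "
                    f"loss={float(loss.data)}, lr={config.learning_rate}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        final_loss = float(np.mean(losses))
        epochs_run = epoch + 1
        if final_loss < best_loss - 1e-5:
            best_loss = final_loss
            stall = 0
        else:
            stall += 1
            if stall >= config.early_stopping_patience:
                break

    model.set_training(False)
    spec = getattr(model, "_spec", None)
    meta = {"seed": config.seed, "epochs_run": epochs_run,
            "final_train_loss": final_loss}
    return TrainedBaseModel(spec=spec, model=model, training_meta=meta)


def predict_proba(trained: TrainedBaseModel | Module, X: np.ndarray,
                  batch_size: int = 256) -> np.ndarray:
    """Probabilities in input order; empty input gives an empty vector."""
    model = trained.model if isinstance(trained, TrainedBaseModel) else trained
    X = np.ascontiguousarray(X, dtype=np.float32)
    if len(X) == 0:
        return np.zeros(0, dtype=np.float64)
    model.set_training(False)
    chunks = []
    for start in range(0, len(X), batch_size):
        prob = model(Tensor(X[start:start + batch_size]))
        chunks.append(prob.data.astype(np.float64))
    return np.concatenate(chunks)


# ---------------------------------------------------------------------
# persistence: directory with a JSON spec sidecar + one npz of weights
# ---------------------------------------------------------------------

def save_trained_model(trained: TrainedBaseModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec = trained.spec
    sidecar = {
        "architecture": spec.architecture,
        "hyperparameters": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in spec.hyperparameters.items()},
        "input_shape": list(spec.input_shape),
        "training_meta": trained.training_meta,
    }
    (directory / "spec.json").write_text(json.dumps(sidecar, indent=2))
    np.savez(directory / "weights.npz", **trained.model.state_dict())


def load_trained_model(directory: str | Path) -> TrainedBaseModel:
    directory = Path(directory)
    sidecar = json.loads((directory / "spec.json").read_text())
    hp = {k: (tuple(v) if isinstance(v, list) else v)
          for k, v in sidecar["hyperparameters"].items()}
    spec = BaseModelSpec(architecture=sidecar["architecture"],
                         hyperparameters=hp,
                         input_shape=tuple(sidecar["input_shape"]))
    model = build_model(spec, seed=0)
    with np.load(directory / "weights.npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    model.set_training(False)
    trained = TrainedBaseModel(spec=spec, model=model,
                               training_meta=sidecar["training_meta"])
    return trained
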