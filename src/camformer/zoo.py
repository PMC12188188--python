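"""Declarative construction of the residual-CNN architecture family.

A :class:`ModelConfig` describes the network; :func:`build_model` realises it
as a predictor f: sequence -> expression.  Named presets (``camformer``,
``camformer_small``, ``camformer_mini``, ``camformer_tiny``) are stored as
JSON data files; the two large presets are pinned by their trainable-parameter
counts (16.6 M and 3.4 M).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np

from .data import EncodedBatch, EncodingScheme, SEQ_LEN
from .nn import ConvNet

PRESETS = ("camformer", "camformer_small", "camformer_mini", "camformer_tiny")


@dataclass
class ModelConfig:
    conv_channels: list[int]
    kernel_sizes: list[int]
    residual_after: list[int] = field(default_factory=list)
    penultimate_maxpool: bool = True
    pool_width: int = 11
    fc_dims: list[int] = field(default_factory=lambda: [64])
    dropout: list[float] = field(default_factory=list)
    activation: str = "relu"
    batchnorm: bool = True
    input_channels: int = 4
    seq_len: int = SEQ_LEN

    def __post_init__(self) -> None:
        if not self.conv_channels:
            raise ValueError("need at least one conv layer")
        if len(self.kernel_sizes) != len(self.conv_channels):
            raise ValueError("kernel_sizes must match conv_channels")
        if any(k % 2 == 0 or k < 1 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be odd and positive")
        if self.activation != "relu":
            raise ValueError("only 'relu' activation is supported")
        n = len(self.conv_channels)
        if any(not 1 <= i <= n for i in self.residual_after):
            raise ValueError(f"residual_after indices must lie in 1..{n}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


class Model:
    """A realised predictor with train/eval mode and opaque learned state."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        self.mode = "eval"
        self.net = ConvNet(
            input_channels=config.input_channels,
            conv_channels=list(config.conv_channels),
            kernel_sizes=list(config.kernel_sizes),
            residual_after=list(config.residual_after),
            batchnorm=config.batchnorm,
            pool_width=config.pool_width if config.penultimate_maxpool else None,
            fc_dims=list(config.fc_dims),
            dropout=list(config.dropout),
            seq_len=config.seq_len,
            seed=seed,
        )

    def train_mode(self) -> "Model":
        self.mode = "train"
        return self

    def eval_mode(self) -> "Model":
        self.mode = "eval"
        return self

    def _as_ncl(self, batch) -> np.ndarray:
        if isinstance(batch, EncodedBatch):
            x = batch.to_ncl()
        else:
            x = np.asarray(batch)
        if x.ndim != 3:
            raise ValueError("expected an EncodedBatch or (n, c, L) array")
        if x.shape[1] != self.config.input_channels:
            raise ValueError(
                f"batch has {x.shape[1]} channels, model expects "
                f"{self.config.input_channels}")
        return x

    def forward(self, batch, batch_size: int = 512) -> np.ndarray:
        """Predict one real value per sequence (eval mode, deterministic)."""
        x = self._as_ncl(batch)
        if x.shape[0] == 0:
            return np.zeros(0)
        outs = [self.net.forward(x[i:i + batch_size], train=False)
                for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs).astype(np.float64)


def build_model(config: ModelConfig, seed: int = 0) -> Model:
    return Model(config, seed=seed)


def count_parameters(model: Model) -> int:
    """Exact number of trainable scalars."""
    return model.net.n_parameters()


def layer_output(model: Model, batch, layer_index: int) -> np.ndarray:
    """Post-activation, post-residual activations of one conv block, in the
    (n, h, w, c) = (n, positions, 1, channels) convention."""
    if not 1 <= layer_index <= model.net.n_conv:
        raise ValueError(
            f"layer_index must be in 1..{model.net.n_conv}, got {layer_index}")
    x = model._as_ncl(batch)
    model.net.forward(x, train=False, capture=True)
    act = model.net.block_outputs[layer_index - 1]  # (n, c, L)
    return np.ascontiguousarray(act.transpose(0, 2, 1))[:, :, None, :]


# --------------------------------------------------------------------------- #
# presets and checkpoints

def load_preset(name: str, encoding: EncodingScheme | str | None = None
                ) -> ModelConfig:
    """Load a named preset, adapting input channels to the encoding scheme."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    text = resources.files("camformer.presets").joinpath(
        f"{name}.json").read_text()
    cfg = ModelConfig.from_dict(json.loads(text))
    if encoding is not None:
        if isinstance(encoding, str):
            encoding = EncodingScheme(encoding)
        cfg.input_channels = encoding.channels
    return cfg


def save_checkpoint(model: Model, path) -> None:
    """Single-file container: config (JSON) + weights + batch-norm state."""
    state = model.net.state_dict()
    np.savez(path, __config__=np.frombuffer(
        model.config.to_json().encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> Model:
    with np.load(path) as zf:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(zf["__config__"]).decode()))
        model = Model(cfg)
        state = {k: zf[k] for k in zf.files if k != "__config__"}
    model.net.load_state_dict(state)
    return model
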