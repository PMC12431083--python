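"""The 4-block Conv1D + channel-attention classifier.

Architecture (per block i = 1..4): Conv1D(f_i filters, kernel k_i, stride 1,
same padding, ReLU) → channel attention (optional per block) → average pooling
(pool 3, stride 2, same padding); the 4th block's pooling is replaced by
global average pooling over the temporal axis.  The pooled 128-vector feeds
Dense(128, ReLU) then Dense(5, softmax).  Defaults: filters (16, 32, 64, 128),
kernels (21, 23, 25, 27), attention after every block with reduction ratio
r = 8.

With 2 input leads and a 720-sample window the network has 307,669 trainable
parameters; with 12 leads and 514 samples, 311,029.  ``summarize`` audits the
per-layer shape/parameter ledger; ``count_parameters`` is its total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import (AvgPool1D, ChannelAttention, Conv1D, Dense, GlobalAvgPool,
                 pool_output_length, sigmoid, softmax)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Declarative architecture description (serializable)."""

    n_leads: int = 2
    window_len: int = 720
    conv_filters: tuple[int, int, int, int] = (16, 32, 64, 128)
    conv_kernels: tuple[int, int, int, int] = (21, 23, 25, 27)
    reduction_ratio: int = 8
    attention_mask: tuple[bool, bool, bool, bool] = (True, True, True, True)
    dense_units: int = 128
    n_classes: int = 5

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 4 or len(self.conv_kernels) != 4:
            raise ConfigurationError("conv_filters and conv_kernels must have length 4")
        if len(self.attention_mask) != 4:
            raise ConfigurationError("attention_mask must have length 4")
        if self.reduction_ratio < 1:
            raise ConfigurationError("reduction ratio must be a positive integer")
        for f, attended in zip(self.conv_filters, self.attention_mask):
            if attended and f // self.reduction_ratio < 1:
                raise ConfigurationError(
                    f"reduction ratio {self.reduction_ratio} leaves no hidden "
                    f"units for attended channel count {f}"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("conv_filters", "conv_kernels", "attention_mask"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


#: configurations matching the two study datasets
MITBIH_CONFIG = ModelConfig(n_leads=2, window_len=720)
INCART_CONFIG = ModelConfig(n_leads=12, window_len=514)


@dataclass(frozen=True)
class LayerSummary:
    name: str
    output_shape: tuple[int, ...]
    n_params: int

    def __post_init__(self) -> None:
        if self.n_params < 0:
            raise ConfigurationError("parameter count must be non-negative")


class Model:
    """A built network: an ordered layer list plus its config."""

    def __init__(self, cfg: ModelConfig, layers: list[nn.Layer]):
        self.cfg = cfg
        self.layers = layers

    # -- inference ----------------------------------------------------------

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """Class probabilities (N × n_classes); each row sums to 1."""
        x = np.asarray(batch, dtype=nn.DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != (self.cfg.window_len, self.cfg.n_leads):
            raise ConfigurationError(
                f"batch shape {x.shape[1:]} does not match configured input "
                f"({self.cfg.window_len}, {self.cfg.n_leads})"
            )
        for layer in self.layers:
            x = layer.forward(x)
        return softmax(x)

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Argmax class indices; ties break toward the lowest class index."""
        return self.forward(batch).argmax(axis=1)

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    # -- audit --------------------------------------------------------------

    def summarize(self) -> list[LayerSummary]:
        """Per-layer output shapes and trainable parameter counts."""
        L, C = self.cfg.window_len, self.cfg.n_leads
        rows: list[LayerSummary] = []
        for layer in self.layers:
            if isinstance(layer, (Conv1D, ChannelAttention, AvgPool1D)):
                L, C = layer.output_shape(L, layer.c_out if isinstance(layer, Conv1D) else C)
                if isinstance(layer, Conv1D):
                    C = layer.c_out
                rows.append(LayerSummary(layer.name, (L, C), layer.n_params()))
            elif isinstance(layer, GlobalAvgPool):
                rows.append(LayerSummary(layer.name, (C,), 0))
            elif isinstance(layer, Dense):
                C = layer.n_out
                rows.append(LayerSummary(layer.name, (C,), layer.n_params()))
        return rows

    def count_parameters(self) -> int:
        return int(sum(layer.n_params() for layer in self.layers))

    def attention_layers(self) -> list[ChannelAttention]:
        return [ly for ly in self.layers if isinstance(ly, ChannelAttention)]

    # -- weight I/O ---------------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for ly in self.layers for p in ly.params.values()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for ly in self.layers for p in ly.params.values()]
        if len(flat) != len(weights):
            raise ConfigurationError(
                f"expected {len(flat)} weight arrays, got {len(weights)}"
            )
        for dst, src in zip(flat, weights):
            if dst.shape != src.shape:
                raise ConfigurationError(
                    f"weight shape mismatch: {dst.shape} vs {src.shape}"
                )
            dst[...] = src.astype(dst.dtype)

    def save(self, path: str | Path) -> Path:
        """Single-file checkpoint (npz) with the config embedded."""
        path = Path(path)
        if path.suffix != ".npz":  # np.savez appends .npz itself
            path = Path(str(path) + ".npz")
        arrays = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        np.savez(path, config=json.dumps(self.cfg.to_dict()), **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "Model":
        with np.load(path, allow_pickle=False) as data:
            cfg = ModelConfig.from_dict(json.loads(str(data["config"])))
            model = build_model(cfg, seed=seed)
            n = len([k for k in data.files if k.startswith("w")])
            model.set_weights([data[f"w{i}"] for i in range(n)])
        return model


def build_model(cfg: ModelConfig, seed: int = 0) -> Model:
    """Assemble the network from its declarative config.

    Weight initialization is Glorot-uniform from a generator seeded with
    ``seed`` (recorded by callers in the run log).
    """
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_in = cfg.n_leads
    for i, (f, k, attended) in enumerate(
        zip(cfg.conv_filters, cfg.conv_kernels, cfg.attention_mask), start=1
    ):
        layers.append(Conv1D(c_in, f, k, rng=rng, name=f"conv{i}"))
        if attended:
            layers.append(
                ChannelAttention(f, cfg.reduction_ratio, rng=rng, name=f"attention{i}")
            )
        if i < 4:
            layers.append(AvgPool1D(name=f"avgpool{i}"))
        c_in = f
    layers.append(GlobalAvgPool(name="global_avgpool"))
    layers.append(Dense(cfg.conv_filters[-1], cfg.dense_units, relu=True,
                        rng=rng, name="dense"))
    layers.append(Dense(cfg.dense_units, cfg.n_classes, rng=rng, name="output"))
    return Model(cfg, layers)


def temporal_lengths(cfg: ModelConfig) -> list[int]:
    """The temporal length after each conv block's pooling stage, starting
    from the input length (the 4th entry is the pre-global-pool length):
    e.g. 720 → 360 → 180 → 90 and 514 → 257 → 129 → 65."""
    lengths = [cfg.window_len]
    L = cfg.window_len
    for _ in range(3):
        L = pool_output_length(L)
        lengths.append(L)
    return lengths


# ---------------------------------------------------------------------------
# Functional attention ops (the core computation, usable standalone)
# ---------------------------------------------------------------------------


@dataclass
class AttentionParams:
    """Bias-free bottleneck MLP weights: W0 is (C/r × C), W1 is (C × C/r)."""

    W0: np.ndarray
    W1: np.ndarray

    def __post_init__(self) -> None:
        self.W0 = np.asarray(self.W0, dtype=np.float64)
        self.W1 = np.asarray(self.W1, dtype=np.float64)
        if self.W0.ndim != 2 or self.W1.ndim != 2 or self.W0.shape[::-1] != self.W1.shape:
            raise ConfigurationError(
                f"inconsistent attention weight shapes {self.W0.shape}, {self.W1.shape}"
            )


def channel_attention(F: np.ndarray, p: AttentionParams) -> np.ndarray:
    """Channel-attention vector A ∈ (0,1)^C for a feature map F (L × C).

    A = σ( W1·relu(W0·mean_t F) + W1·relu(W0·max_t F) ): the shared MLP is
    applied to the average- and max-pooled channel descriptors separately and
    the results are summed before the sigmoid.
    """
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 2:
        raise ConfigurationError("feature map must be 2-D (L × C)")
    C = F.shape[1]
    if p.W0.shape[1] != C:
        raise ConfigurationError(
            f"attention weights expect {p.W0.shape[1]} channels, feature map has {C}"
        )
    d_avg = F.mean(axis=0)
    d_max = F.max(axis=0)
    h = p.W1 @ np.maximum(p.W0 @ d_avg, 0.0) + p.W1 @ np.maximum(p.W0 @ d_max, 0.0)
    return sigmoid(h)


def refine(F: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Refined feature map: output[t, c] = A[c] · F[t, c]."""
    F = np.asarray(F)
    A = np.asarray(A)
    if F.ndim != 2 or A.ndim != 1 or A.shape[0] != F.shape[1]:
        raise ConfigurationError(
            f"attention vector length {A.shape} does not match feature map {F.shape}"
        )
    return F * A[None, :]
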