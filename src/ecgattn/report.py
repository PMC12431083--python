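"""Interpretability export, complexity report, and the ablation harness."""

from __future__ import annotations

import logging
import os
import tempfile
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import confusion, micro_metrics
from .model import Model, ModelConfig, build_model
from .preprocessing import SegmentDataset
from .training import TrainConfig, train

logger = logging.getLogger(__name__)

#: incremental attention placements: 0 layers up to all four conv blocks
ATTENTION_PLACEMENTS: tuple[tuple[bool, bool, bool, bool], ...] = (
    (False, False, False, False),
    (True, False, False, False),
    (True, True, False, False),
    (True, True, True, False),
    (True, True, True, True),
)

REDUCTION_RATIOS = (6, 7, 8, 9, 10)
BATCH_SIZES = (8, 16, 32, 64)
LEARNING_RATES = (1e-1, 1e-2, 1e-3, 1e-4, 1e-5)

ABLATION_AXES: dict[str, tuple] = {
    "attention_layers": ATTENTION_PLACEMENTS,
    "reduction_ratio": REDUCTION_RATIOS,
    "batch_size": BATCH_SIZES,
    "learning_rate": LEARNING_RATES,
}


@dataclass
class AttentionProfile:
    """Per attended layer: the channel gate vector A for one input segment."""

    layer_names: list[str]
    attention: list[np.ndarray]  # one (C,) vector per attended layer

    def to_frame(self) -> pd.DataFrame:
        """Heatmap-ready long table: (layer, channel, weight)."""
        rows = [
            {"layer": name, "channel": c, "weight": float(w)}
            for name, vec in zip(self.layer_names, self.attention)
            for c, w in enumerate(vec)
        ]
        return pd.DataFrame(rows, columns=["layer", "channel", "weight"])


def attention_profile(model: Model, segment: np.ndarray) -> AttentionProfile:
    """Evaluate the model on one segment and collect every attended layer's
    channel-attention vector (values in (0, 1))."""
    attended = model.attention_layers()
    if not attended:
        logger.warning("model has no attention layers; profile is empty")
        return AttentionProfile([], [])
    model.forward(np.asarray(segment)[None])
    return AttentionProfile(
        [ly.name for ly in attended],
        [ly.last_attention[0].astype(np.float64).copy() for ly in attended],
    )


@dataclass(frozen=True)
class ComplexityReport:
    n_parameters: int
    model_size_mb: float
    inference_ms: float | None
    repetitions: int


def complexity_report(model: Model, repetitions: int = 100) -> ComplexityReport:
    """Parameter count, serialized checkpoint size, and mean single-segment
    inference time over ``repetitions`` (hardware-dependent; ``repetitions=0``
    omits timing)."""
    with tempfile.TemporaryDirectory() as tmp:
        ckpt = model.save(os.path.join(tmp, "model"))
        size_mb = os.path.getsize(ckpt) / 1e6
    timing = None
    if repetitions > 0:
        x = np.zeros((1, model.cfg.window_len, model.cfg.n_leads), dtype=np.float32)
        model.forward(x)  # warm-up
        t0 = time.perf_counter()
        for _ in range(repetitions):
            model.forward(x)
        timing = (time.perf_counter() - t0) / repetitions * 1000.0
    return ComplexityReport(model.count_parameters(), size_mb, timing, repetitions)


@dataclass(frozen=True)
class AblationGrid:
    """One ablation axis and the values to sweep (defaults to the standard
    grid for that axis); ``seeds`` gives the replication seeds per point."""

    axis: str
    values: tuple = ()
    seeds: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if self.axis not in ABLATION_AXES:
            raise ValueError(
                f"unknown ablation axis {self.axis!r}; one of {sorted(ABLATION_AXES)}"
            )
        if not self.values:
            object.__setattr__(self, "values", ABLATION_AXES[self.axis])


@dataclass
class AblationPoint:
    axis: str
    value: object
    seed: int
    accuracy: float | None
    error: str | None = None


def _apply_point(axis: str, value, model_cfg: ModelConfig, train_cfg: TrainConfig,
                 seed: int) -> tuple[ModelConfig, TrainConfig]:
    from dataclasses import replace

    train_cfg = replace(train_cfg, seed=seed)
    if axis == "attention_layers":
        return replace(model_cfg, attention_mask=tuple(value)), train_cfg
    if axis == "reduction_ratio":
        # channel counts (16..128) are divisible by 8 only among the standard
        # ratios; non-divisors fall back to floor division inside the layer
        return replace(model_cfg, reduction_ratio=int(value)), train_cfg
    if axis == "batch_size":
        return model_cfg, replace(train_cfg, batch_size=int(value))
    return model_cfg, replace(train_cfg, learning_rate=float(value))


def run_ablation(
    grid: AblationGrid,
    train_ds: SegmentDataset,
    val_ds: SegmentDataset,
    test_ds: SegmentDataset,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> pd.DataFrame:
    """Train and evaluate once per grid point per seed, all other settings at
    their defaults; returns a table (axis, value, seed, accuracy).  Failures
    at individual points are recorded and the sweep continues."""
    points: list[AblationPoint] = []
    for value in grid.values:
        for seed in grid.seeds:
            try:
                mcfg, tcfg = _apply_point(grid.axis, value, model_cfg, train_cfg, seed)
                model = build_model(mcfg, seed=seed)
                model, _ = train(model, train_ds, val_ds, tcfg)
                preds = model.predict(test_ds.X)
                cm = confusion(test_ds.y, preds, K=mcfg.n_classes)
                acc = micro_metrics(cm)["accuracy"]
                points.append(AblationPoint(grid.axis, value, seed, acc))
            except Exception as exc:  # keep sweeping; surface per-point failure
                logger.error("ablation point %s=%r seed %d failed: %s",
                             grid.axis, value, seed, exc)
                points.append(AblationPoint(grid.axis, value, seed, None, str(exc)))
    return pd.DataFrame(
        [
            {"axis": p.axis, "value": str(p.value), "seed": p.seed,
             "accuracy": p.accuracy, "error": p.error}
            for p in points
        ]
    )
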