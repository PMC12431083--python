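"""Beat-anchored segmentation and dataset splitting.

Each annotated beat whose symbol maps to an AAMI class yields one fixed-length
window of ``round(window_seconds * fs)`` samples centred on the beat
(2 s by default: 720 samples at 360 Hz, 514 at 257 Hz).  Windows that would
cross a record boundary are discarded by default (``edge_policy="discard"``)
or zero-padded on request.  The pooled dataset is shuffled with a seeded
generator and cut into contiguous train/validation/test slices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import AAMI_CLASSES, AAMIMap, ECGRecord, map_symbol

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class Segment:
    """One labelled window: ``window`` is L × C in mV, ``label`` an AAMI class
    index into :data:`~ecgattn.records.AAMI_CLASSES`, and ``anchor_index`` the
    0-based sample of the anchoring beat in the source record."""

    window: np.ndarray
    label: int
    record_id: str
    anchor_index: int


@dataclass
class SegmentDataset:
    """A stack of N equally shaped windows with labels and provenance."""

    X: np.ndarray  # (N, L, C)
    y: np.ndarray  # (N,) int labels into class_names
    class_names: tuple[str, ...] = AAMI_CLASSES
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y, dtype=np.int64)
        if len(self.X) != len(self.y) or len(self.X) != len(self.provenance):
            raise ConfigurationError(
                f"inconsistent dataset lengths: X={len(self.X)} y={len(self.y)} "
                f"provenance={len(self.provenance)}"
            )

    def __len__(self) -> int:
        return len(self.y)

    def class_counts(self) -> dict[str, int]:
        return {
            name: int((self.y == k).sum()) for k, name in enumerate(self.class_names)
        }

    def subset(self, idx: np.ndarray) -> "SegmentDataset":
        return SegmentDataset(
            self.X[idx], self.y[idx], self.class_names,
            [self.provenance[i] for i in idx],
        )


@dataclass(frozen=True)
class SplitConfig:
    """Train/validation/test fractions (must sum to 1) and the shuffle seed."""

    train: float = 0.6
    val: float = 0.2
    test: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.train, self.val, self.test):
            if not 0.0 < f < 1.0:
                raise ConfigurationError(f"split fraction {f} outside (0, 1)")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")


def window_length(fs: float, window_seconds: float = 2.0) -> int:
    """Samples per window: round(window_seconds × fs)."""
    return int(round(window_seconds * fs))


def segment_record(
    record: ECGRecord,
    profile: AAMIMap,
    window_seconds: float = 2.0,
    edge_policy: str = "discard",
) -> list[Segment]:
    """Cut one beat-centred window per mapped beat annotation.

    The window starts at ``anchor − floor(L/2)`` and covers L consecutive
    samples; its label is the anchor beat's AAMI class.  Beats whose symbol
    does not map under ``profile`` are skipped.  Beats whose window would
    extend past either record boundary are discarded (default) or zero-padded
    when ``edge_policy="zero_pad"``.
    """
    if window_seconds <= 0:
        raise ConfigurationError("window_seconds must be > 0")
    if edge_policy not in ("discard", "zero_pad"):
        raise ConfigurationError(f"unknown edge_policy {edge_policy!r}")
    L = window_length(record.fs, window_seconds)
    T, C = record.signals.shape
    if L > T and edge_policy == "discard":
        logger.warning(
            "window of %d samples longer than record %s (%d samples); no segments",
            L, record.record_id, T,
        )
        return []
    half = L // 2
    segments: list[Segment] = []
    for ann in record.annotations:
        cls = map_symbol(ann.symbol, profile)
        if cls is None:
            continue
        start = ann.sample_index - half
        stop = start + L
        if start < 0 or stop > T:
            if edge_policy == "discard":
                continue
            window = np.zeros((L, C), dtype=record.signals.dtype)
            lo, hi = max(start, 0), min(stop, T)
            window[lo - start : hi - start] = record.signals[lo:hi]
        else:
            window = record.signals[start:stop].copy()
        segments.append(
            Segment(window, AAMI_CLASSES.index(cls), record.record_id, ann.sample_index)
        )
    return segments


def assemble_dataset(
    records: Sequence[ECGRecord],
    profile: AAMIMap,
    window_seconds: float = 2.0,
    edge_policy: str = "discard",
) -> SegmentDataset:
    """Segment every record and stack the windows in record order.

    All records must share sampling rate and lead count (the model input shape
    is fixed per dataset).
    """
    if records:
        fs0, c0 = records[0].fs, records[0].n_leads
        for rec in records:
            if rec.fs != fs0 or rec.n_leads != c0:
                raise ConfigurationError(
                    f"record {rec.record_id}: fs={rec.fs}/C={rec.n_leads} differs "
                    f"from fs={fs0}/C={c0}"
                )
        L = window_length(fs0, window_seconds)
        C = c0
    else:
        L = C = 0
    segs: list[Segment] = []
    for rec in records:
        segs.extend(segment_record(rec, profile, window_seconds, edge_policy))
    if segs:
        X = np.stack([s.window for s in segs])
        y = np.array([s.label for s in segs], dtype=np.int64)
    else:
        X = np.zeros((0, L, C))
        y = np.zeros(0, dtype=np.int64)
    ds = SegmentDataset(X, y, AAMI_CLASSES, [(s.record_id, s.anchor_index) for s in segs])
    logger.info("assembled %d segments; per-class counts %s", len(ds), ds.class_counts())
    return ds


def split_sizes(n: int, cfg: SplitConfig) -> tuple[int, int, int]:
    """Slice sizes for an n-segment dataset: ``floor(f_train·n)`` training
    segments, ``round(f_val·n)`` validation, remainder test.  (At the MIT-BIH
    scale of n = 109,373 this yields 65,623 / 21,875 / 21,875.)"""
    n_train = int(np.floor(cfg.train * n))
    n_val = int(round(cfg.val * n))
    n_val = min(n_val, n - n_train)
    return n_train, n_val, n - n_train - n_val


def shuffle_split(
    ds: SegmentDataset, cfg: SplitConfig
) -> tuple[SegmentDataset, SegmentDataset, SegmentDataset]:
    """Seed-determined uniform shuffle followed by contiguous slicing.

    The three parts partition the dataset (no overlap, no loss); the same seed
    always produces the identical partition.
    """
    n = len(ds)
    if n < 3:
        raise ConfigurationError(f"need at least 3 segments to split, got {n}")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_train, n_val, _ = split_sizes(n, cfg)
    idx_train = perm[:n_train]
    idx_val = perm[n_train : n_train + n_val]
    idx_test = perm[n_train + n_val :]
    return ds.subset(idx_train), ds.subset(idx_val), ds.subset(idx_test)


def one_hot(y: np.ndarray, K: int = 5) -> np.ndarray:
    """One-hot encode integer labels; each row has exactly one 1."""
    y = np.asarray(y, dtype=np.int64)
    if y.size and (y.min() < 0 or y.max() >= K):
        bad = y[(y < 0) | (y >= K)][0]
        raise ConfigurationError(f"label {bad} outside 0..{K - 1}")
    out = np.zeros((len(y), K), dtype=np.float32)
    out[np.arange(len(y)), y] = 1.0
    return out
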