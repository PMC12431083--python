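"""Annotated multi-lead ECG records: container types, AAMI class mapping, and I/O.

A record is a ``T × C`` signal matrix in millivolts with a sampling rate and a
list of per-beat annotations (sample index + single-character PhysioNet beat
symbol).  Two on-disk layouts are supported:

* the PhysioNet WFDB layout (``.hea`` header, binary ``.dat`` signal in format
  16 or 212, MIT-format ``.atr`` annotations) for real Holter accessions such
  as MIT-BIH (2 leads @ 360 Hz) and St. Petersburg INCART (12 leads @ 257 Hz);
* a plain-text fixture layout (CSV signal + JSON manifest) used for tests and
  synthetic data — inspectable and diff-able.

Beat symbols are reduced to the five AAMI heartbeat classes
(N = normal, S = supraventricular ectopic, V = ventricular ectopic,
F = fusion, Q = unknown/paced) through dataset-specific symbol profiles.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

AAMI_CLASSES: tuple[str, ...] = ("N", "S", "V", "F", "Q")

#: symbols the WFDB convention treats as heartbeats (everything else — rhythm
#: changes, noise, comments — is a non-beat annotation and is dropped on read)
BEAT_SYMBOLS = frozenset("NLRBAaJSVrFejnE/fQ")

# MIT .atr annotation type codes -> mnemonic symbols (ecgcodes convention)
_ATR_CODE_TO_SYMBOL: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "[", 32: "]", 33: "e", 34: "n", 35: "@",
    36: "x", 37: "f", 38: "(", 39: ")", 40: "r",
}


class ValidationError(ValueError):
    """A record or annotation violates a structural invariant."""


class FixtureParseError(ValueError):
    """A fixture file is malformed; the message carries file/field context."""


@dataclass(frozen=True)
class BeatAnnotation:
    """One annotated heartbeat: 0-based sample index of the fiducial point
    (≈ R-peak) and its single-character PhysioNet beat symbol."""

    sample_index: int
    symbol: str

    def __post_init__(self) -> None:
        if self.sample_index < 0:
            raise ValidationError(f"annotation sample_index {self.sample_index} < 0")
        if not self.symbol:
            raise ValidationError("annotation symbol must be non-empty")


@dataclass
class ECGRecord:
    """A multi-lead ECG record with per-beat annotations.

    Attributes
    ----------
    record_id : str
        Identifier (e.g. the WFDB record name).
    fs : float
        Sampling rate in Hz, > 0.
    signals : ndarray, shape (T, C)
        Signal matrix in mV; T samples by C leads.
    lead_names : sequence of str, length C
        Lead identities (metadata only; the model consumes leads positionally).
    annotations : sequence of BeatAnnotation
        Beat annotations, strictly increasing by sample index, all in [0, T).
    """

    record_id: str
    fs: float
    signals: np.ndarray
    lead_names: Sequence[str]
    annotations: Sequence[BeatAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValidationError(f"signals must be 2-D (T × C), got {self.signals.ndim}-D")
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signals.shape[1]

    def validate(self) -> None:
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        T, C = self.signals.shape
        if T < 1 or C < 1:
            raise ValidationError(f"signals must be at least 1 × 1, got {T} × {C}")
        if len(self.lead_names) != C:
            raise ValidationError(
                f"{len(self.lead_names)} lead names for {C} signal columns"
            )
        prev = -1
        for ann in self.annotations:
            if ann.sample_index >= T:
                raise ValidationError(
                    f"annotation at sample {ann.sample_index} beyond record "
                    f"length {T}"
                )
            if ann.sample_index <= prev:
                raise ValidationError(
                    f"annotations not strictly increasing at sample {ann.sample_index}"
                )
            prev = ann.sample_index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ECGRecord):
            return NotImplemented
        return (
            self.record_id == other.record_id
            and self.fs == other.fs
            and self.signals.shape == other.signals.shape
            and np.array_equal(self.signals, other.signals)
            and list(self.lead_names) == list(other.lead_names)
            and list(self.annotations) == list(other.annotations)
        )


# ---------------------------------------------------------------------------
# AAMI symbol profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AAMIMap:
    """Mapping from raw beat symbols to the 5 AAMI classes for one dataset.

    ``mapping`` covers exactly the active symbol set of the profile; symbols
    outside it map to ``None`` ("skip this beat"), never to an error.
    """

    name: str
    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        for sym, cls in self.mapping.items():
            if cls not in AAMI_CLASSES:
                raise ValidationError(f"symbol {sym!r} maps to unknown class {cls!r}")

    @property
    def active_symbols(self) -> frozenset[str]:
        return frozenset(self.mapping)


#: the 15 MIT-BIH beat subtypes and their AAMI classes
MITBIH_PROFILE = AAMIMap(
    "mitbih",
    {
        "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
        "A": "S", "a": "S", "J": "S", "S": "S",
        "V": "V", "E": "V",
        "F": "F",
        "/": "Q", "f": "Q", "Q": "Q",
    },
)

#: the 8 beat subtypes present in the INCART accession
INCART_PROFILE = AAMIMap(
    "incart",
    {
        "N": "N", "R": "N", "j": "N",
        "A": "S", "S": "S",
        "V": "V",
        "F": "F",
        "Q": "Q",
    },
)

PROFILES: dict[str, AAMIMap] = {"mitbih": MITBIH_PROFILE, "incart": INCART_PROFILE}


def map_symbol(symbol: str, profile: AAMIMap) -> str | None:
    """Return the AAMI class for ``symbol`` under ``profile``, or ``None`` if
    the symbol is outside the profile's active set (beat skipped downstream)."""
    return profile.mapping.get(symbol)


# ---------------------------------------------------------------------------
# WFDB reading (header + signal formats 16/212 + MIT-format annotations)
# ---------------------------------------------------------------------------


def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FixtureParseError(f"{hea_path}: empty header")
    head = lines[0].split()
    record_name = head[0].split("/")[0]
    nsig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    nsamp = int(head[3]) if len(head) > 3 else 0
    sig_specs = []
    for ln in lines[1 : 1 + nsig]:
        parts = ln.split()
        fname = parts[0]
        fmt_field = parts[1]
        fmt = int(fmt_field.split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, None, "mV"
        if len(parts) > 2:
            g = parts[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, base = g.rstrip(")").split("(")
                baseline = int(base)
            gain = float(g) if float(g) != 0 else 200.0
        adczero = int(parts[4]) if len(parts) > 4 else 0
        if baseline is None:
            baseline = adczero
        desc = " ".join(parts[8:]) if len(parts) > 8 else fname
        sig_specs.append(
            {"fname": fname, "fmt": fmt, "gain": gain, "baseline": baseline,
             "units": units, "desc": desc}
        )
    return record_name, nsig, fs, nsamp, sig_specs


def _read_dat(dat_path: Path, fmt: int, nsig: int, nsamp: int) -> np.ndarray:
    raw = dat_path.read_bytes()
    if fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2")
    elif fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        n_pairs = len(b) // 3
        b = b[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        adc = np.empty(2 * n_pairs, dtype=np.int32)
        adc[0::2] = s0
        adc[1::2] = s1
        adc[adc > 2047] -= 4096  # 12-bit two's complement
    else:
        raise FixtureParseError(f"{dat_path}: unsupported WFDB signal format {fmt}")
    total = nsig * nsamp if nsamp else (len(adc) // nsig) * nsig
    return adc[:total].reshape(-1, nsig)


def _read_atr(atr_path: Path) -> list[BeatAnnotation]:
    data = atr_path.read_bytes()
    anns: list[BeatAnnotation] = []
    t = 0
    i = 0
    n = len(data) // 2 * 2
    while i + 1 < n:
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if code == 0 and delta == 0:  # end of file
            break
        if code == 59:  # SKIP: 4-byte interval, high word first
            (hi,) = struct.unpack_from("<H", data, i)
            (lo,) = struct.unpack_from("<H", data, i + 2)
            i += 4
            interval = (hi << 16) | lo
            if interval >= 1 << 31:
                interval -= 1 << 32
            t += interval
        elif code in (60, 61, 62):  # NUM / SUB / CHN: modifiers, no time advance
            continue
        elif code == 63:  # AUX: delta = byte count, padded to even
            i += delta + (delta & 1)
        else:
            t += delta
            sym = _ATR_CODE_TO_SYMBOL.get(code)
            if sym is not None and sym in BEAT_SYMBOLS:
                anns.append(BeatAnnotation(t, sym))
    return anns


def read_wfdb_record(path: str | Path, annotation_extension: str = "atr") -> ECGRecord:
    """Read a PhysioNet WFDB record (``.hea`` + ``.dat`` + annotation file).

    ``path`` is the record path without extension.  Signal formats 16 and 212
    are supported (these cover the MIT-BIH and INCART accessions).  Only
    beat-typed annotations are kept; rhythm/quality/comment annotations are
    dropped at this boundary.

    Raises
    ------
    FileNotFoundError
        if any of the three component files is missing.
    ValidationError
        if an annotation index lies beyond the signal length (the message
        names the offending index).
    """
    base = Path(path)
    hea = base.with_suffix(".hea")
    atr = base.with_suffix(f".{annotation_extension}")
    for p in (hea, atr):
        if not p.exists():
            raise FileNotFoundError(f"missing WFDB component file: {p}")
    record_name, nsig, fs, nsamp, specs = _parse_header(hea)
    dat = base.parent / specs[0]["fname"]
    if not dat.exists():
        raise FileNotFoundError(f"missing WFDB component file: {dat}")
    fmt = specs[0]["fmt"]
    adc = _read_dat(dat, fmt, nsig, nsamp)
    gains = np.array([s["gain"] for s in specs])
    baselines = np.array([s["baseline"] for s in specs])
    signals = (adc - baselines) / gains  # ADC units -> mV
    anns = _read_atr(atr)
    return ECGRecord(
        record_id=record_name,
        fs=fs,
        signals=signals,
        lead_names=[s["desc"] for s in specs],
        annotations=anns,
    )


# ---------------------------------------------------------------------------
# Fixture format: CSV signal + JSON manifest
# ---------------------------------------------------------------------------


def write_fixture(record: ECGRecord, path: str | Path) -> Path:
    """Write ``record`` to ``path`` (a directory) in the plain-text fixture
    layout: ``signal.csv`` (one row per sample, one column per lead, full
    ``repr`` float precision) plus ``manifest.json``.  Returns ``path``."""
    record.validate()
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "signal.csv", "w") as fh:
        fh.write(",".join(record.lead_names) + "\n")
        for row in record.signals:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
    manifest = {
        "record_id": record.record_id,
        "fs": record.fs,
        "lead_names": list(record.lead_names),
        "n_samples": record.n_samples,
        "annotations": [[a.sample_index, a.symbol] for a in record.annotations],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_fixture(path: str | Path) -> ECGRecord:
    """Read a fixture directory written by :func:`write_fixture`.

    The round trip is lossless: indices and symbols compare exactly and
    signal values are restored to full stored precision.
    """
    src = Path(path)
    man_path = src / "manifest.json"
    sig_path = src / "signal.csv"
    try:
        manifest = json.loads(man_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FixtureParseError(f"{man_path}: {exc}") from exc
    lines = sig_path.read_text().splitlines()
    if not lines:
        raise FixtureParseError(f"{sig_path}: empty signal file")
    header = lines[0].split(",")
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        vals = ln.split(",")
        if len(vals) != len(header):
            raise FixtureParseError(
                f"{sig_path}:{lineno}: expected {len(header)} fields, got {len(vals)}"
            )
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise FixtureParseError(f"{sig_path}:{lineno}: {exc}") from exc
    signals = np.array(rows, dtype=np.float64)
    try:
        anns = [BeatAnnotation(int(i), str(s)) for i, s in manifest["annotations"]]
    except (KeyError, TypeError) as exc:
        raise FixtureParseError(f"{man_path}: bad annotations field: {exc}") from exc
    return ECGRecord(
        record_id=manifest["record_id"],
        fs=manifest["fs"],
        signals=signals,
        lead_names=manifest["lead_names"],
        annotations=anns,
    )


def count_classes(
    records: Iterable[ECGRecord], profile: AAMIMap
) -> dict[str, int]:
    """Per-AAMI-class beat counts over ``records`` (beats whose symbol is
    outside the profile are not counted)."""
    counts = {c: 0 for c in AAMI_CLASSES}
    for rec in records:
        for ann in rec.annotations:
            cls = map_symbol(ann.symbol, profile)
            if cls is not None:
                counts[cls] += 1
    return counts
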