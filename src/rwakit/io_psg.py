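"""Polysomnography I/O: EDF signals, hypnograms, and result tables.

Signals are read from EDF/EDF+ through MNE and carried as :class:`EmgSignal`
in microvolts. Sleep staging is carried as :class:`Hypnogram`, one stage code
per 30-s epoch, using the R&K-style codes ``W, REM, S1, S2, S3`` (AASM
``N1..N3``/``R`` tokens are accepted on input). All intervals are half-open
``[start, end)`` in seconds from recording start; epoch ``k`` covers
``[k*epoch_len, (k+1)*epoch_len)``.

A small plain-EDF writer is included so synthetic recordings and test
fixtures can round-trip through the same on-disk format real data arrives in.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

__all__ = [
    "EmgSignal",
    "Hypnogram",
    "PSGRecording",
    "ChannelNotFoundError",
    "AmbiguousChannelError",
    "HypnogramParseError",
    "STAGES",
    "read_edf",
    "write_edf",
    "read_hypnogram",
    "write_hypnogram",
    "resample",
    "load_recording",
    "write_subject_json",
    "write_cohort_csv",
    "COHORT_COLUMNS",
]

#: Canonical stage vocabulary (stored form).
STAGES = ("W", "REM", "S1", "S2", "S3")

_STAGE_ALIASES = {
    "W": "W", "WAKE": "W", "WK": "W", "0": "W",
    "R": "REM", "REM": "REM", "5": "REM",
    "S1": "S1", "N1": "S1", "1": "S1",
    "S2": "S2", "N2": "S2", "2": "S2",
    "S3": "S3", "N3": "S3", "3": "S3",
}


class ChannelNotFoundError(KeyError):
    """No channel label matched the requested pattern."""


class AmbiguousChannelError(KeyError):
    """More than one channel label matched the requested pattern."""


class HypnogramParseError(ValueError):
    """A stage file could not be interpreted."""


def _map_stage(token: str, where: str) -> str:
    key = token.strip().upper()
    # EDF+ style "Sleep stage N2" annotations
    if key.startswith("SLEEP STAGE"):
        key = key[len("SLEEP STAGE"):].strip()
    if key not in _STAGE_ALIASES:
        raise HypnogramParseError(
            f"unknown sleep-stage token {token!r} at {where}; "
            f"expected one of W, REM/R, S1-S3, N1-N3"
        )
    return _STAGE_ALIASES[key]


@dataclass
class EmgSignal:
    """A uniformly sampled EMG trace in microvolts."""

    samples: np.ndarray
    rate: float
    label: str = "EMG"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.rate


@dataclass
class Hypnogram:
    """Sleep stages on a fixed epoch grid starting at time 0."""

    stages: tuple
    epoch_len: float = 30.0

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        if not self.stages:
            raise ValueError("hypnogram must contain at least one epoch")
        if not self.epoch_len > 0:
            raise ValueError("epoch_len must be positive")
        bad = sorted({s for s in self.stages if s not in STAGES})
        if bad:
            raise ValueError(f"invalid stage codes {bad}; allowed: {STAGES}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len

    def stage_at(self, t: float) -> str:
        """Stage of the epoch containing time ``t`` (half-open epochs)."""
        if not 0 <= t < self.duration_s:
            raise ValueError(f"time {t} outside hypnogram span")
        return self.stages[int(t // self.epoch_len)]

    def epochs_of(self, stage: str) -> list:
        return [k for k, s in enumerate(self.stages) if s == stage]

    def stage_seconds(self, stage: str) -> float:
        if stage == "NREM":
            return sum(self.stage_seconds(s) for s in ("S1", "S2", "S3"))
        return len(self.epochs_of(stage)) * self.epoch_len


@dataclass
class PSGRecording:
    """One subject's signals plus staging."""

    signals: list
    hypnogram: Hypnogram
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.signals:
            raise ValueError("recording needs at least one signal")
        longest = max(s.duration_s for s in self.signals)
        if self.hypnogram.duration_s > longest + self.hypnogram.epoch_len:
            raise ValueError(
                "hypnogram span exceeds signal span by more than one epoch"
            )

    def chin(self, pattern: str = "chin") -> EmgSignal:
        return _match_one(self.signals, pattern)


def _match_one(signals: Sequence[EmgSignal], pattern: str) -> EmgSignal:
    pat = pattern.lower()
    hits = [s for s in signals if pat in s.label.lower()]
    if not hits:
        raise ChannelNotFoundError(
            f"no channel matches {pattern!r}; available: "
            f"{[s.label for s in signals]}"
        )
    if len(hits) > 1:
        raise AmbiguousChannelError(
            f"pattern {pattern!r} matches several channels: "
            f"{[s.label for s in hits]}"
        )
    return hits[0]


# ---------------------------------------------------------------------------
# EDF reading (MNE) and a minimal plain-EDF writer
# ---------------------------------------------------------------------------

_VOLTAGE_DIMS = {"uv", "µv", "mv", "v"}


def _edf_physical_dims(path: Path) -> dict:
    """Channel label -> physical-dimension string from the EDF header."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        ns = int(header[252:256].decode("ascii").strip())
        per = fh.read(256 * ns)
    labels = [per[16 * i:16 * (i + 1)].decode("ascii", "replace").strip()
              for i in range(ns)]
    off = 16 * ns + 80 * ns
    dims = [per[off + 8 * i: off + 8 * (i + 1)]
            .decode("ascii", "replace").strip() for i in range(ns)]
    return dict(zip(labels, dims))


def read_edf(path, channel: str = "chin") -> EmgSignal:
    """Read one channel from an EDF/EDF+ file, case-insensitive substring match.

    The returned samples are in microvolts at the channel's native rate;
    channels recorded in mV or V are converted.  Channels whose physical
    dimension is not a voltage are passed through with a warning and
    assumed to already be µV.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    pat = channel.lower()
    hits = [name for name in raw.ch_names if pat in name.lower()]
    if not hits:
        raise ChannelNotFoundError(
            f"no channel matches {channel!r}; available: {raw.ch_names}"
        )
    if len(hits) > 1:
        raise AmbiguousChannelError(
            f"pattern {channel!r} matches several channels: {hits}"
        )
    name = hits[0]
    raw = mne.io.read_raw_edf(
        str(path), include=[name], preload=True, verbose="error"
    )
    data = raw.get_data(picks=[0])[0]
    dim = _edf_physical_dims(path).get(name, "")
    if dim.lower() in _VOLTAGE_DIMS:
        data = data * 1e6      # MNE normalises voltage channels to volts
    else:
        warnings.warn(
            f"channel {name!r} has physical dimension {dim!r}; "
            "assuming values are already in µV"
        )
    return EmgSignal(samples=data, rate=float(raw.info["sfreq"]), label=name)


def _pack(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def _fmt_phys(v: float) -> str:
    """Format a physical min/max into EDF's 8-char ASCII field."""
    for fmt in ("%.6g", "%.5g", "%.4g", "%.3g", "%.2g"):
        s = fmt % v
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot format {v} in 8 chars")


def edf_quantization_step(samples: np.ndarray) -> float:
    """Amplitude resolution a round-trip through :func:`write_edf` incurs."""
    pmin, pmax = _phys_range(np.asarray(samples, dtype=float))
    return (pmax - pmin) / 65535.0


def _phys_range(x: np.ndarray) -> tuple:
    amax = float(max(np.max(np.abs(x)), 1e-3)) * 1.0000001
    # use the *formatted* values so writer and reader agree exactly
    pmax = float(_fmt_phys(amax))
    if pmax < amax:  # formatting rounded down; bump to keep samples in range
        pmax = float(_fmt_phys(amax * 1.01))
    return -pmax, pmax


def write_edf(path, signals, *, patient_id: str = "X", recording_id: str = "X",
              start: str = "01.01.00 00.00.00") -> None:
    """Write signals to a plain EDF file (16-bit, physical unit µV).

    Each signal must have an integer sampling rate; the data record length is
    one second and the final record is zero-padded, so durations that are not
    whole seconds read back padded to the next second.
    """
    if isinstance(signals, EmgSignal):
        signals = [signals]
    for s in signals:
        if abs(s.rate - round(s.rate)) > 1e-9:
            raise ValueError("EDF writer requires integer sampling rates")
    n_records = max(int(math.ceil(s.duration_s)) for s in signals)
    ns = len(signals)

    date_s, time_s = start.split(" ")
    header = b"".join([
        _pack("0", 8),
        _pack(patient_id, 80),
        _pack(recording_id, 80),
        _pack(date_s, 8),
        _pack(time_s, 8),
        _pack(str(256 * (ns + 1)), 8),
        _pack("", 44),
        _pack(str(n_records), 8),
        _pack("1", 8),
        _pack(str(ns), 4),
    ])

    phys = [_phys_range(s.samples) for s in signals]
    per_sig = b"".join([
        b"".join(_pack(s.label[:16], 16) for s in signals),
        b"".join(_pack("", 80) for _ in signals),
        b"".join(_pack("uV", 8) for _ in signals),
        b"".join(_pack(_fmt_phys(p[0]), 8) for p in phys),
        b"".join(_pack(_fmt_phys(p[1]), 8) for p in phys),
        b"".join(_pack("-32768", 8) for _ in signals),
        b"".join(_pack("32767", 8) for _ in signals),
        b"".join(_pack("", 80) for _ in signals),
        b"".join(_pack(str(int(round(s.rate))), 8) for s in signals),
        b"".join(_pack("", 32) for _ in signals),
    ])

    digital = []
    for s, (pmin, pmax) in zip(signals, phys):
        spr = int(round(s.rate))
        x = np.zeros(n_records * spr)
        x[: s.n] = s.samples
        gain = (pmax - pmin) / 65535.0
        d = np.clip(np.round((x - pmin) / gain) - 32768, -32768, 32767)
        digital.append(d.astype("<i2").reshape(n_records, spr))

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        for rec in range(n_records):
            for d in digital:
                fh.write(d[rec].tobytes())


# ---------------------------------------------------------------------------
# Hypnograms
# ---------------------------------------------------------------------------

def read_hypnogram(path, dialect: str = "auto", epoch_len: float = 30.0) -> Hypnogram:
    """Read staging from ``csv`` (onset_seconds,stage), ``txt`` (one token per
    epoch line) or ``edf_annotations`` (EDF+ "Sleep stage ..." annotations)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        suffix = path.suffix.lower()
        dialect = {"csv": "csv", "txt": "txt", "edf": "edf_annotations"}.get(
            suffix.lstrip("."), "csv"
        )
    if dialect == "edf_annotations":
        return _read_hypnogram_edf(path, epoch_len)
    if dialect not in ("csv", "txt"):
        raise ValueError(f"unknown hypnogram dialect {dialect!r}")

    rows: list = []
    with open(path, newline="") as fh:
        if dialect == "csv":
            for i, row in enumerate(csv.reader(fh), start=1):
                if not row or not "".join(row).strip():
                    continue
                if len(row) < 2:
                    raise HypnogramParseError(f"line {i}: expected onset,stage")
                if i == 1 and not _is_number(row[0]):
                    continue  # header row
                rows.append((float(row[0]), _map_stage(row[1], f"line {i}")))
        else:
            for i, line in enumerate(fh, start=1):
                tok = line.strip()
                if tok:
                    rows.append(((len(rows)) * epoch_len,
                                 _map_stage(tok, f"line {i}")))
    if not rows:
        raise HypnogramParseError(f"{path}: no stage entries found")
    rows.sort(key=lambda r: r[0])
    stages = []
    for onset, stage in rows:
        k = int(round(onset / epoch_len))
        if abs(onset - k * epoch_len) > 1e-6:
            raise HypnogramParseError(
                f"onset {onset} not aligned to the {epoch_len}-s epoch grid"
            )
        if k != len(stages):
            raise HypnogramParseError(
                f"epochs not contiguous from 0: onset {onset} is epoch {k}, "
                f"expected epoch {len(stages)}"
            )
        stages.append(stage)
    return Hypnogram(stages=tuple(stages), epoch_len=epoch_len)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _read_hypnogram_edf(path: Path, epoch_len: float) -> Hypnogram:
    import mne

    ann = mne.read_annotations(str(path))
    if len(ann) == 0:
        raise HypnogramParseError(f"{path}: no annotations found")
    stages: dict = {}
    for onset, duration, desc in zip(ann.onset, ann.duration, ann.description):
        if "stage" not in desc.lower() and desc.strip().upper() not in _STAGE_ALIASES:
            continue
        code = _map_stage(desc, f"annotation at {onset:.1f}s")
        n = max(1, int(round((duration or epoch_len) / epoch_len)))
        k0 = int(round(onset / epoch_len))
        for k in range(k0, k0 + n):
            stages[k] = code
    if not stages:
        raise HypnogramParseError(f"{path}: no sleep-stage annotations found")
    n_epochs = max(stages) + 1
    missing = [k for k in range(n_epochs) if k not in stages]
    if missing:
        raise HypnogramParseError(
            f"{path}: staging not contiguous, missing epochs {missing[:5]}..."
        )
    return Hypnogram(
        stages=tuple(stages[k] for k in range(n_epochs)), epoch_len=epoch_len
    )


def write_hypnogram(path, hyp: Hypnogram, dialect: str = "csv") -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if dialect == "csv":
            w = csv.writer(fh)
            for k, stage in enumerate(hyp.stages):
                w.writerow([f"{k * hyp.epoch_len:g}", stage])
        elif dialect == "txt":
            fh.write("\n".join(hyp.stages) + "\n")
        else:
            raise ValueError(f"unknown hypnogram dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Resampling and convenience loading
# ---------------------------------------------------------------------------

def resample(sig: EmgSignal, target_rate: float) -> EmgSignal:
    """Band-limited (polyphase) resampling to ``target_rate``."""
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if abs(target_rate - sig.rate) < 1e-9:
        return sig
    frac = Fraction(target_rate / sig.rate).limit_denominator(10_000)
    y = resample_poly(sig.samples, frac.numerator, frac.denominator)
    return EmgSignal(samples=y, rate=float(target_rate), label=sig.label,
                     start_time=sig.start_time)


def load_recording(edf_path, hypnogram_path, *, channel: str = "chin",
                   hypnogram_dialect: str = "auto",
                   target_rate: float | None = 256.0,
                   meta: Mapping | None = None) -> PSGRecording:
    """Read an EDF chin channel plus staging into a :class:`PSGRecording`.

    By default the signal is resampled to the package's canonical 256 Hz so
    the 51-sample analysis window spans a fixed ~0.2 s regardless of the
    recorder's native rate.
    """
    sig = read_edf(edf_path, channel)
    if target_rate is not None:
        sig = resample(sig, target_rate)
    hyp = read_hypnogram(hypnogram_path, hypnogram_dialect)
    return PSGRecording(signals=[sig], hypnogram=hyp, meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "subject", "group", "auto_rwa", "tonic_pct", "phasic_pct", "any_pct",
] + [
    f"{stage}_{metric}"
    for stage in ("REM", "S1", "S2", "S3", "NREM")
    for metric in ("pct_miniepochs", "duration_s", "pct_duration")
]


def write_subject_json(path, payload: Mapping) -> None:
    with open(path, "w") as fh:
        json.dump(dict(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_cohort_csv(path, rows: Iterable[Mapping]) -> None:
    df = pd.DataFrame(list(rows))
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)
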