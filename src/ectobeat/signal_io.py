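"""Record / annotation containers and file I/O.

Multichannel physiological records (ECG lead II, PPG, optionally an arterial
blood pressure channel) are held in a :class:`Record`.  Two on-disk formats
are supported:

* **csv** — one named column per channel, a mandatory header row, '.' decimal
  separator; the sampling rate, subject id and channel units live in a JSON
  sidecar ``<stem>.meta.json``.  Round trips are bit-exact.
* **wfdb** — a minimal WFDB-compatible pair ``<stem>.hea`` / ``<stem>.dat``
  (format 16, interleaved little-endian int16 with per-channel gain and
  baseline).  Round trips are lossless up to the declared ADC resolution.

Beat annotations travel as CSV with columns ``sample,label``.  Sample indices
are 0-based everywhere; intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Channel names a Record may carry.
KNOWN_CHANNELS = ("ecg", "ppg", "abp")

#: Sentinel class for beats excluded from training/evaluation.
EXCLUDED = "excluded"

#: AAMI-style grouping of WFDB beat symbols onto the three-class scheme.
#: Sinus-node and escape beats -> N; atrial/junctional prematures -> S
#: (supraventricular ectopic); ventricular ectopics -> V.  Everything else
#: (paced, fusion, artefact, ...) is excluded.
SYMBOL_MAP: Mapping[str, str] = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
}


class RecordError(ValueError):
    """Malformed record or file contents."""


class ChannelMissingError(RecordError):
    """A required channel is absent from the source file."""


@dataclass
class Record:
    """Synchronized multichannel signal container.

    Parameters
    ----------
    subject_id:
        Free-text identifier of the measured subject.
    fs:
        Sampling rate in Hz, shared by all channels; must be > 0.
    channels:
        Mapping from channel name (subset of :data:`KNOWN_CHANNELS`) to a
        1-D float array.  All channels must have identical length, and the
        record must span at least ~3 s (a three-beat buffer).
    units:
        Per-channel unit label, e.g. ``{"ecg": "mV", "ppg": "a.u."}``.
    """

    subject_id: str
    fs: float
    channels: dict[str, np.ndarray]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self.validate()

    def validate(self) -> None:
        if self.fs <= 0:
            raise RecordError(f"sampling rate must be > 0, got {self.fs}")
        if not self.channels:
            raise RecordError("record has no channels")
        lengths = {k: len(v) for k, v in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise RecordError(f"unequal channel lengths: {lengths}")
        n = next(iter(lengths.values()))
        if n < 3 * self.fs:
            raise RecordError(
                f"record too short: {n} samples < 3 s at fs={self.fs} Hz"
            )
        for k, v in self.channels.items():
            if v.ndim != 1:
                raise RecordError(f"channel {k!r} is not 1-D")

    def __len__(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise ChannelMissingError(f"channel-missing: {name!r}")
        return self.channels[name]


@dataclass(frozen=True)
class BeatAnnotation:
    """One annotated beat: 0-based sample index + class symbol (N/S/V)."""

    sample: int
    label: str


@dataclass
class AnnotationSet:
    """Ordered beat annotations for one record."""

    record_id: str
    beats: list[BeatAnnotation]

    def __post_init__(self) -> None:
        samples = [b.sample for b in self.beats]
        if any(s2 <= s1 for s1, s2 in zip(samples, samples[1:])):
            raise RecordError("annotations must be strictly increasing in sample")

    @property
    def samples(self) -> np.ndarray:
        return np.array([b.sample for b in self.beats], dtype=int)

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.beats]

    def __len__(self) -> int:
        return len(self.beats)


def map_symbols(symbols: Iterable[str]) -> list[str]:
    """Map WFDB beat symbols onto {N, S, V}; unknown symbols -> ``excluded``.

    Total and idempotent on {N, S, V}.  The number of unmapped symbols is
    logged, never raised.
    """
    out = []
    unknown = 0
    for s in symbols:
        mapped = SYMBOL_MAP.get(s, EXCLUDED)
        if mapped == EXCLUDED:
            unknown += 1
        out.append(mapped)
    if unknown:
        logger.info("map_symbols: %d symbol(s) mapped to %r", unknown, EXCLUDED)
    return out


# ---------------------------------------------------------------------------
# CSV format
# ---------------------------------------------------------------------------

def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".meta.json")


def _write_csv(record: Record, path: Path) -> None:
    df = pd.DataFrame(record.channels)
    # float_format=None + repr round-trip: pandas writes repr(float) which
    # parses back bit-exactly.
    df.to_csv(path, index=False)
    meta = {
        "subject_id": record.subject_id,
        "fs": record.fs,
        "units": record.units,
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1))


def _read_csv(path: Path, fs: float | None) -> Record:
    df = pd.read_csv(path, float_precision="round_trip")
    meta_file = _meta_path(path)
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    if fs is None:
        fs = meta.get("fs")
    if fs is None:
        raise RecordError(f"no sampling rate: pass fs= or provide {meta_file.name}")
    channels = {c: df[c].to_numpy(dtype=float) for c in df.columns}
    return Record(
        subject_id=str(meta.get("subject_id", path.stem)),
        fs=float(fs),
        channels=channels,
        units=dict(meta.get("units", {})),
    )


# ---------------------------------------------------------------------------
# Minimal WFDB (format 16) support
# ---------------------------------------------------------------------------

_ADC_MAX = 32000  # headroom below int16 limits


def _write_wfdb(record: Record, path: Path) -> None:
    stem = path.with_suffix("")
    names = list(record.channels)
    n = len(record)
    gains, baselines, digital = [], [], []
    for name in names:
        x = record.channels[name]
        span = np.max(np.abs(x))
        gain = _ADC_MAX / span if span > 0 else 1.0
        gains.append(gain)
        baselines.append(0)
        digital.append(np.round(x * gain).astype(np.int16))
    interleaved = np.stack(digital, axis=1).reshape(-1)
    dat_name = stem.name + ".dat"
    lines = [f"{stem.name} {len(names)} {record.fs:g} {n}"]
    for name, gain, base in zip(names, gains, baselines):
        unit = record.units.get(name, "a.u.")
        lines.append(
            f"{dat_name} 16 {gain:.12g}({base})/{unit} 16 0 0 0 0 {name}"
        )
    stem.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    interleaved.astype("<i2").tofile(stem.with_suffix(".dat"))


def _read_wfdb(path: Path) -> Record:
    stem = path.with_suffix("")
    header = stem.with_suffix(".hea").read_text().strip().splitlines()
    rec_line = header[0].split()
    nsig, fs, n = int(rec_line[1]), float(rec_line[2]), int(rec_line[3])
    raw = np.fromfile(stem.with_suffix(".dat"), dtype="<i2")
    if len(raw) != nsig * n:
        raise RecordError(
            f"wfdb .dat length {len(raw)} != {nsig} signals x {n} samples"
        )
    frames = raw.reshape(n, nsig)
    channels, units = {}, {}
    for j, line in enumerate(header[1 : 1 + nsig]):
        fields = line.split()
        gain_field = fields[2]  # gain(baseline)/units
        gain_s, rest = gain_field.split("(")
        base_s, unit = rest.split(")/")
        name = fields[-1]
        gain, base = float(gain_s), int(base_s)
        channels[name] = (frames[:, j].astype(float) - base) / gain
        units[name] = unit
    return Record(subject_id=stem.name, fs=fs, channels=channels, units=units)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_record(
    path: str | Path,
    format: str = "csv",
    fs: float | None = None,
    require: Sequence[str] = (),
) -> Record:
    """Read a multichannel record.

    Parameters
    ----------
    path:
        File path (.csv, or the .hea/.dat stem for wfdb).
    format:
        ``"csv"`` or ``"wfdb"``.
    fs:
        Sampling rate override for csv files without a sidecar.
    require:
        Channel names that must be present; a missing one raises
        :class:`ChannelMissingError` naming the channel.
    """
    path = Path(path)
    if not (path.exists() or path.with_suffix(".hea").exists()):
        raise FileNotFoundError(path)
    if format == "csv":
        rec = _read_csv(path, fs)
    elif format == "wfdb":
        rec = _read_wfdb(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    for name in require:
        if name not in rec.channels:
            raise ChannelMissingError(f"channel-missing: {name!r}")
    return rec


def write_record(record: Record, path: str | Path, format: str = "csv") -> None:
    """Write a record; the result is readable by :func:`read_record`.

    Raises on non-finite samples — silently quantizing NaNs would corrupt
    downstream delineation.
    """
    record.validate()
    for name, x in record.channels.items():
        if not np.all(np.isfinite(x)):
            raise RecordError(f"non-finite samples in channel {name!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        _write_csv(record, path)
    elif format == "wfdb":
        _write_wfdb(record, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_annotations(path: str | Path, record_id: str = "") -> AnnotationSet:
    """Read a ``sample,label`` CSV into an :class:`AnnotationSet`."""
    df = pd.read_csv(path)
    beats = [
        BeatAnnotation(int(s), str(l))
        for s, l in zip(df["sample"], df["label"])
    ]
    return AnnotationSet(record_id=record_id or Path(path).stem, beats=beats)


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {"sample": annotations.samples, "label": annotations.labels}
    )
    df.to_csv(path, index=False)
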