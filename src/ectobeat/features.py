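"""The 20 amplitude-invariant multimodal beat features.

Per beat, 14 ECG features and 6 PPG features are computed from the signal
between the preceding and following R peaks (plus the next pulse), ordered:

=====  ==========================================================
 f1    preceding / following RR-interval ratio
 f2    ECG heartbeat power (normalized window)
 f3    ECG heartbeat mean (normalized window)
 f4    ECG heartbeat max/|min| ratio
 f5–f14  ECG samples at 10 equally spaced points around the R peak
 f15–f17 PPG fractional amplitudes at 25/50/75 % of pulse duration
 f18   PPG pulse-wave power (normalized pulse)
 f19   PPG pulse-wave mean (normalized pulse)
 f20   current / next PPG pulse-peak amplitude ratio
=====  ==========================================================

Amplitude invariance: the ECG window is de-meaned and divided by the R-peak
amplitude; the PPG pulse is referenced to its onset baseline and divided by
the peak-minus-onset amplitude.  Gain and offset on either channel then
cancel exactly, so no inter-beat normalization is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .delineation import DelineatedBeat
from .signal_io import Record

N_FEATURES = 20
ECG_FEATURES = slice(0, 14)   # f1..f14
PPG_FEATURES = slice(14, 20)  # f15..f20

#: Relative amplitude floor: eps = EPS_REL * channel dynamic range.
EPS_REL = 1e-6

#: Window extent around the R peak, as fractions of the neighbouring RR
#: intervals: [r - 0.35*RRprec, r + 0.65*RRfoll].
WINDOW_BEFORE = 0.35
WINDOW_AFTER = 0.65

#: Pulse-duration fractions for the fractional-amplitude features f15-f17.
FRACTIONAL_POSITIONS = (0.25, 0.50, 0.75)


class BeatExcluded(ValueError):
    """Beat cannot yield a feature vector (flat window/pulse, no fiducials)."""


@dataclass
class FeatureVector:
    """The 20 ordered features of one beat, with its source-beat index."""

    f: np.ndarray
    beat_ref: int

    @property
    def ecg(self) -> np.ndarray:
        return self.f[ECG_FEATURES]

    @property
    def ppg(self) -> np.ndarray:
        return self.f[PPG_FEATURES]


def ecg_window(beat: DelineatedBeat, fs: float) -> tuple[int, int]:
    """Half-open analysis window [start, end) around the beat's R peak."""
    start = int(round(beat.r - WINDOW_BEFORE * beat.rr_prec * fs))
    end = int(round(beat.r + WINDOW_AFTER * beat.rr_foll * fs))
    return start, end


def _eps(channel: np.ndarray) -> float:
    rng = float(np.ptp(channel))
    return EPS_REL * rng if rng > 0 else EPS_REL


def compute_ecg_features(ecg: np.ndarray, beat: DelineatedBeat, fs: float) -> np.ndarray:
    """f1..f14 for one valid beat; raises :class:`BeatExcluded` on a flat window."""
    ecg = np.asarray(ecg, dtype=float)
    start, end = ecg_window(beat, fs)
    if start < 0 or end > len(ecg) or end - start < 2:
        raise BeatExcluded(f"window [{start},{end}) outside record")
    eps = _eps(ecg[start:end])
    w = ecg[start:end] - np.mean(ecg[start:end])
    amp = abs(w[beat.r - start])
    if amp < eps:
        amp = float(np.max(np.abs(w)))
        if amp < eps:
            raise BeatExcluded("zero-amplitude ECG window")
    u = w / amp

    f = np.empty(14)
    f[0] = beat.rr_prec / beat.rr_foll
    f[1] = float(np.mean(u**2))
    f[2] = float(np.mean(u))
    f[3] = float(np.max(u) / max(abs(np.min(u)), 1e-6))
    # 10 equally spaced sampling positions spanning the window, linearly
    # interpolated at fractional indices.
    pos = np.arange(10) * (end - start - 1) / 9.0
    f[4:14] = np.interp(pos, np.arange(end - start), u)
    return f


def compute_ppg_features(ppg: np.ndarray, beat: DelineatedBeat, fs: float) -> np.ndarray:
    """f15..f20 for one beat with complete PPG fiducials."""
    ppg = np.asarray(ppg, dtype=float)
    if not beat.ppg_complete:
        raise BeatExcluded("missing PPG fiducials")
    eps = _eps(ppg[beat.ppg_onset : beat.ppg_onset_next + 1])
    o, o2 = beat.ppg_onset, beat.ppg_onset_next
    baseline = ppg[o]
    amp = ppg[beat.ppg_peak] - baseline
    if amp <= eps:
        raise BeatExcluded("pulse-too-flat")
    amp_next = ppg[beat.ppg_peak_next] - ppg[o2]
    if amp_next <= eps:
        raise BeatExcluded("pulse-too-flat (next pulse)")

    pulse = ppg[o:o2]
    v = (pulse - baseline) / amp
    duration = o2 - o

    f = np.empty(6)
    # Fractional amplitudes at 25/50/75 % of pulse duration (interpolated).
    for j, q in enumerate(FRACTIONAL_POSITIONS):
        f[j] = float(np.interp(q * duration, np.arange(duration), v))
    f[3] = float(np.mean(v**2))
    f[4] = float(np.mean(v))
    f[5] = float(amp / amp_next)
    return f


def compute_feature_vector(record: Record, beat: DelineatedBeat) -> FeatureVector:
    """All 20 features of one beat; propagates exclusion flags."""
    if not beat.valid:
        raise BeatExcluded("invalid (boundary) beat")
    f = np.concatenate(
        [
            compute_ecg_features(record.channel("ecg"), beat, record.fs),
            compute_ppg_features(record.channel("ppg"), beat, record.fs),
        ]
    )
    if not np.all(np.isfinite(f)):
        raise BeatExcluded("non-finite feature value")
    return FeatureVector(f=f, beat_ref=beat.r)


def extract_features(
    record: Record, beats: list[DelineatedBeat]
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix for all extractable beats.

    Returns ``(X, idx)`` where ``X`` is (n_beats, 20) and ``idx`` holds the
    positions of the retained beats in ``beats``; excluded beats (boundary,
    flat pulse, incomplete fiducials) are silently dropped.
    """
    rows, idx = [], []
    for i, beat in enumerate(beats):
        try:
            rows.append(compute_feature_vector(record, beat).f)
        except BeatExcluded:
            continue
        idx.append(i)
    if not rows:
        return np.empty((0, N_FEATURES)), np.array([], dtype=int)
    return np.vstack(rows), np.array(idx, dtype=int)
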