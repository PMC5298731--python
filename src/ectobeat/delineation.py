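"""Beat delineation: ECG R peaks, PPG pulse peaks and onsets.

R peaks come from the Pan–Tompkins cascade (5–15 Hz band-pass, derivative,
squaring, 150 ms moving-window integration, dual adaptive thresholds with
search-back), refined to the raw-ECG local maximum so that "R-peak
amplitude" is well defined.  Pulse peaks are a plain maximum search between
adjacent R peaks; pulse onsets come from a foot-minimum search or the
intersecting-tangent construction (the record pipeline's default, being
robust to zero-phase filter smear at low SNR).

All sample indices are 0-based; intervals are half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import Record

logger = logging.getLogger(__name__)

# Classic Pan-Tompkins constants.
BAND_HZ = (5.0, 15.0)
INTEGRATION_S = 0.150
REFRACTORY_S = 0.200
THRESH_SIGNAL_UPDATE = 0.125
THRESH_NOISE_UPDATE = 0.25
SEARCHBACK_RR_FACTOR = 1.66
REFINE_S = 0.025  # refine fiducial to raw local max within +/-25 ms


@dataclass
class DelineatedBeat:
    """Fiducials of one heartbeat with its RR context.

    ``r_prev < r < r_next`` holds for every valid beat; RR intervals are in
    seconds.  ``ppg_peak``/``ppg_onset`` belong to the pulse launched by this
    beat (they lie in ``(r, r_next)``); the ``*_next`` fields describe the
    following pulse and may be missing for the last interior beat, in which
    case ``ppg_complete`` is False and the beat is excluded from PPG feature
    extraction.
    """

    r: int
    r_prev: int = -1
    r_next: int = -1
    rr_prec: float = np.nan
    rr_foll: float = np.nan
    ppg_peak: int = -1
    ppg_peak_next: int = -1
    ppg_onset: int = -1
    ppg_onset_next: int = -1
    valid: bool = False
    ppg_complete: bool = False


def _bandpass(ecg: np.ndarray, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    b, a = sps.butter(2, [BAND_HZ[0] / nyq, BAND_HZ[1] / nyq], btype="band")
    return sps.filtfilt(b, a, ecg)


def smooth_ppg(
    ppg: np.ndarray, fs: float, band_hz: tuple[float, float] = (0.4, 12.0)
) -> np.ndarray:
    """Zero-phase band-pass used before PPG fiducial localization.

    The low edge strips baseline wander (which would drag the foot minimum
    off the flat diastolic runoff); the high edge suppresses broadband
    noise without moving the systolic upstroke.
    """
    nyq = fs / 2.0
    b, a = sps.butter(2, [band_hz[0] / nyq, band_hz[1] / nyq], btype="band")
    return sps.filtfilt(b, a, ppg)


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Pan–Tompkins QRS detection.

    Returns strictly increasing sample indices with >= 200 ms separation,
    each refined to the raw-ECG local maximum within +/-25 ms of the
    integrated-window fiducial.  An (all-)constant signal yields an empty
    array with a warning.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz, got {fs}")
    if not np.all(np.isfinite(ecg)):
        raise ValueError("ECG contains non-finite samples")
    if np.ptp(ecg) == 0:
        logger.warning("detect_r_peaks: constant signal, no peaks")
        return np.array([], dtype=int)

    filtered = _bandpass(ecg, fs)
    deriv = np.gradient(filtered) * fs
    squared = deriv**2
    win = max(1, int(round(INTEGRATION_S * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if len(cand) == 0:
        return np.array([], dtype=int)

    # Dual adaptive thresholds on the integrated signal.
    spki = float(np.max(mwi[: int(2 * fs)]) * 0.5) if len(mwi) else 0.0
    npki = float(np.mean(mwi[: int(2 * fs)]) * 0.5)
    threshold = npki + 0.25 * (spki - npki)

    accepted: list[int] = []
    rr_history: list[float] = []
    last_accepted_cand_idx = -1
    i = 0
    while i < len(cand):
        c = cand[i]
        if mwi[c] > threshold:
            accepted.append(c)
            spki = THRESH_SIGNAL_UPDATE * mwi[c] + (1 - THRESH_SIGNAL_UPDATE) * spki
            if len(accepted) >= 2:
                rr_history.append((accepted[-1] - accepted[-2]) / fs)
                rr_history = rr_history[-8:]
            last_accepted_cand_idx = i
        else:
            npki = THRESH_NOISE_UPDATE * mwi[c] + (1 - THRESH_NOISE_UPDATE) * npki
            # Search-back: if the expected beat is overdue, re-examine the
            # strongest skipped candidate at half threshold.
            if rr_history and accepted:
                rr_avg = float(np.mean(rr_history))
                if (c - accepted[-1]) / fs > SEARCHBACK_RR_FACTOR * rr_avg:
                    skipped = [
                        j for j in range(last_accepted_cand_idx + 1, i + 1)
                        if cand[j] - accepted[-1] >= refractory
                    ]
                    if skipped:
                        best = max(skipped, key=lambda j: mwi[cand[j]])
                        if mwi[cand[best]] > threshold / 2:
                            accepted.append(int(cand[best]))
                            spki = (
                                THRESH_SIGNAL_UPDATE * mwi[cand[best]]
                                + (1 - THRESH_SIGNAL_UPDATE) * spki
                            )
                            rr_history.append((accepted[-1] - accepted[-2]) / fs)
                            rr_history = rr_history[-8:]
                            last_accepted_cand_idx = best
        threshold = npki + 0.25 * (spki - npki)
        i += 1

    # Refine to raw-signal local maximum within +/-25 ms.
    half = int(round(REFINE_S * fs))
    refined = []
    for c in accepted:
        lo, hi = max(0, c - half), min(len(ecg), c + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.array(sorted(set(refined)), dtype=int)
    # Enforce refractory after refinement (keep the larger raw amplitude).
    keep: list[int] = []
    for r in refined:
        if keep and r - keep[-1] < refractory:
            if ecg[r] > ecg[keep[-1]]:
                keep[-1] = int(r)
        else:
            keep.append(int(r))
    return np.array(keep, dtype=int)


def detect_ppg_peaks(
    ppg: np.ndarray,
    r_peaks: np.ndarray,
    fs: float | None = None,
    blank_s: float = 0.0,
) -> np.ndarray:
    """Pulse peaks: argmax of the PPG in each [r_i, r_{i+1}) interval.

    Ties break to the earliest index (np.argmax semantics).  Returns one
    peak per RR interval (len(r_peaks) - 1 values).  ``blank_s`` skips the
    first part of each interval during the search (a peripheral pulse
    cannot arrive immediately after ventricular contraction; the record
    pipeline uses 180 ms so that the decaying previous pulse and its
    dicrotic wave cannot shadow a small premature one).
    """
    ppg = np.asarray(ppg, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(r_peaks) < 2:
        raise ValueError("need >= 2 R peaks")
    blank = int(round(blank_s * fs)) if (blank_s > 0 and fs) else 0
    peaks = np.empty(len(r_peaks) - 1, dtype=int)
    for i, (a, b) in enumerate(zip(r_peaks[:-1], r_peaks[1:])):
        lo = min(a + blank, b - 1)
        peaks[i] = lo + int(np.argmax(ppg[lo:b]))
    return peaks


def detect_ppg_onsets(
    ppg: np.ndarray,
    r_peaks: np.ndarray,
    ppg_peaks: np.ndarray,
    method: str = "foot_min",
    fs: float | None = None,
    upslope_anchor_s: float | None = None,
) -> np.ndarray:
    """Pulse onsets (feet), one per detected pulse peak.

    ``foot_min``: argmin of the PPG over [r_i, peak_i].  ``tangent``:
    intersection of the horizontal line through that minimum with the
    tangent at the maximum-upslope point of the rising edge, rounded to the
    nearest sample; degenerate (flat) upstrokes fall back to foot_min with a
    warning.  The onset is strictly before its peak.

    With ``upslope_anchor_s`` set (requires ``fs``), the search is anchored
    to the systolic upstroke instead of the whole RR interval: the
    maximum-upslope point is located within that window before the peak
    and the foot minimum is taken just before it.  This keeps the foot of
    a small premature pulse from being undercut by the filtered
    undershoot of the much larger preceding pulse.
    """
    if method not in ("foot_min", "tangent"):
        raise ValueError(f"unknown onset method {method!r}")
    ppg = np.asarray(ppg, dtype=float)
    onsets = np.empty(len(ppg_peaks), dtype=int)
    anchor = int(round(upslope_anchor_s * fs)) if (upslope_anchor_s and fs) else None
    foot_back = int(round(0.06 * fs)) if fs else None
    for i, (r, p) in enumerate(zip(r_peaks[:-1], ppg_peaks)):
        if p <= r:
            onsets[i] = r
            continue
        if anchor:
            lo = max(r, p - anchor)
            slope_seg = np.diff(ppg[lo : p + 1])
            m = lo + int(np.argmax(slope_seg)) if len(slope_seg) else lo
            f_lo = max(r, m - (foot_back or 0))
            foot = f_lo + int(np.argmin(ppg[f_lo : m + 1]))
        else:
            foot = r + int(np.argmin(ppg[r : p + 1]))
        if method == "foot_min" or p - foot < 2:
            onsets[i] = min(foot, p - 1)
            continue
        rise = ppg[foot : p + 1]
        slope = np.diff(rise)
        k = int(np.argmax(slope))
        s = slope[k]
        if s <= 0:
            logger.warning("flat upstroke at pulse %d; falling back to foot_min", i)
            onsets[i] = foot
            continue
        # Tangent at maximum-upslope point (foot+k, rise[k]) intersected with
        # the horizontal line through the foot minimum.
        x_star = (foot + k) - (rise[k] - rise[0]) / s
        onsets[i] = int(np.clip(round(x_star), r, p - 1))
    return onsets


def segment_beats(
    r_peaks: np.ndarray,
    ppg_peaks: np.ndarray,
    ppg_onsets: np.ndarray,
    fs: float,
) -> list[DelineatedBeat]:
    """Assemble one :class:`DelineatedBeat` per interior R peak.

    The first and last R peaks lack a neighbour and are not emitted as
    beats; fewer than 3 R peaks yields an empty list.  RR fields are in
    seconds.  ``ppg_complete`` additionally requires the *next* pulse's peak
    and onset (needed by the pulse-amplitude-ratio feature), which the last
    interior beat lacks.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(r_peaks) < 3:
        return []
    beats = []
    n_pulses = len(ppg_peaks)
    for i in range(1, len(r_peaks) - 1):
        b = DelineatedBeat(
            r=int(r_peaks[i]),
            r_prev=int(r_peaks[i - 1]),
            r_next=int(r_peaks[i + 1]),
            rr_prec=(r_peaks[i] - r_peaks[i - 1]) / fs,
            rr_foll=(r_peaks[i + 1] - r_peaks[i]) / fs,
        )
        if i < n_pulses:
            b.ppg_peak = int(ppg_peaks[i])
            b.ppg_onset = int(ppg_onsets[i])
        if i + 1 < n_pulses:
            b.ppg_peak_next = int(ppg_peaks[i + 1])
            b.ppg_onset_next = int(ppg_onsets[i + 1])
        b.valid = b.ppg_peak >= 0 and b.r < b.ppg_onset <= b.ppg_peak < b.r_next
        b.ppg_complete = b.valid and b.ppg_onset_next >= 0
        beats.append(b)
    return beats


PPG_BLANK_S = 0.180  # no peripheral pulse arrival within 180 ms of the R peak


def delineate_record(
    record: Record,
    onset_method: str = "tangent",
    smooth: bool = True,
) -> list[DelineatedBeat]:
    """Full delineation of a record: R peaks, pulse peaks/onsets, beats.

    PPG fiducials are localized on a zero-phase band-passed (0.4-12 Hz)
    copy of the PPG when ``smooth`` is set; feature extraction still sees
    the original samples.  The intersecting-tangent onset is the default:
    extrapolating the maximum upstroke back to the foot baseline is
    first-order immune to the smearing the zero-phase filter applies to
    the foot minimum, which biases the plain minimum search under noise.
    """
    ecg = record.channel("ecg")
    ppg = record.channel("ppg")
    r = detect_r_peaks(ecg, record.fs)
    if len(r) < 3:
        return []
    p = smooth_ppg(ppg, record.fs) if smooth else ppg
    peaks = detect_ppg_peaks(p, r, fs=record.fs, blank_s=PPG_BLANK_S)
    onsets = detect_ppg_onsets(
        p, r, peaks, method=onset_method, fs=record.fs, upslope_anchor_s=0.15
    )
    return segment_beats(r, peaks, onsets, record.fs)
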