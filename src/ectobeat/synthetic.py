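"""Seeded generator of multi-subject ECG/PPG/ABP records with ground truth.

The generator emulates the signal properties that the detector and the
blood-pressure-estimation (BPE) experiment rely on:

* a sinus beat train with AR(1) RR variability;
* premature **VEBs** (no P wave, broad high-energy QRS, inverted T, full
  compensatory pause: preceding + following RR = 2x the sinus RR) and
  **SVEBs** (premature, morphologically normal QRS, non-compensatory
  pause), never adjacent to another ectopic;
* an SBP/DBP ground-truth trace (baseline + slow drift + respiratory
  modulation) coupled to per-beat pulse arrival time through the
  exponential elasticity law  E_inc = E0 * exp(alpha * P)  and the
  Moens-Korteweg relation  v = sqrt(h * E_inc / (2 * r * rho)),  so that
  PAT = L / v(SBP) (+ pre-ejection jitter): higher pressure -> stiffer
  wall -> faster pulse -> shorter PAT;
* a PPG rendered as per-beat pulses (quarter-sine systolic upstroke,
  exponential diastolic decay, dicrotic bump) whose foot sits at
  R time + PAT, whose amplitude scales with the preceding RR interval
  (stroke-volume proxy, strongly reduced for ectopic pulses, potentiated
  for the following beat) and whose systolic width is modulated by SBP so
  that pulse-morphology BPE carries signal;
* an ABP channel whose per-beat max/min equal the ground-truth SBP/DBP;
* additive white noise at a configurable SNR plus sinusoidal baseline
  wander.

Everything is deterministic under (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .signal_io import AnnotationSet, BeatAnnotation, Record

ECG_WAVES = {
    # (amplitude mV, center offset s, width s) relative to the R peak
    "P": (0.12, -0.18, 0.025),
    "Q": (-0.10, -0.035, 0.010),
    "R": (1.00, 0.0, 0.011),
    "S": (-0.18, 0.035, 0.010),
    "T": (0.35, 0.28, 0.055),
}


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults define the standard study conditions."""

    fs: float = 500.0
    duration_s: float = 300.0
    hr_bpm: float = 72.0
    rr_ar1: float = 0.4            # AR(1) coefficient of RR fluctuation
    rr_sigma_s: float = 0.025      # stationary SD of RR fluctuation
    p_veb: float = 0.05            # per-beat ventricular-ectopic probability
    p_sveb: float = 0.05           # per-beat supraventricular probability
    prematurity: float = 0.60      # mean ectopic coupling interval / sinus RR
    prematurity_sd: float = 0.10   # per-ectopic coupling spread (clipped 0.5-0.9)
    veb_qrs_width: float = 1.8
    veb_qrs_amp: float = 1.4
    ectopic_pulse_amp: float = 0.30     # pulse-amplitude factor at nominal coupling
    sveb_amp_slope: float = 2.2         # SVEB amplitude recovery per coupling ratio
    post_ectopic_amp: float = 1.20
    # Elasticity / Moens-Korteweg ground-truth coupling
    e0_pa: float = 6351.0          # gives PAT ~ 250 ms at SBP 120 mmHg
    alpha_per_mmhg: float = 0.017
    wall_h_m: float = 0.001
    radius_m: float = 0.004
    rho_kg_m3: float = 1060.0
    path_l_m: float = 0.6
    # blood pressure trace
    sbp_base_mmhg: float = 120.0
    sbp_drift_mmhg: float = 8.0
    sbp_drift_period_s: float = 120.0
    sbp_resp_mmhg: float = 2.5
    resp_hz: float = 0.25
    pulse_pressure_mmhg: float = 40.0
    # pulse-arrival timing
    pep_jitter_s: float = 0.005    # pre-ejection-period jitter (PAT != PTT)
    ectopic_pep_shift_s: float = 0.030  # delayed ejection on ectopic beats
    ectopic_pep_jitter_s: float = 0.020  # erratic ectopic ejection timing
    # PPG morphology: quarter-sine upstroke, two-phase diastolic decay
    # (steep post-systolic drop + slow diastolic runoff) and a dicrotic bump.
    ppg_rise_s: float = 0.10
    ppg_decay_fast_s: float = 0.04
    ppg_decay_slow_s: float = 0.40
    ppg_decay_slow_frac: float = 0.30
    ppg_dicrotic_amp: float = 0.10
    ppg_width_sbp_coeff: float = 0.005  # fractional width change per mmHg
    ppg_amp_jitter: float = 0.08
    # noise / interference
    snr_db: float = 20.0
    wander_amp_ecg: float = 0.10
    wander_amp_ppg: float = 0.05
    wander_hz: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_veb <= 1 and 0 <= self.p_sveb <= 1):
            raise ValueError("ectopic probabilities must be in [0,1]")
        if self.p_veb + self.p_sveb >= 0.5:
            raise ValueError("p_veb + p_sveb must be < 0.5")
        for name in ("fs", "duration_s", "hr_bpm", "e0_pa", "wall_h_m",
                     "radius_m", "rho_kg_m3", "path_l_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class GroundTruth:
    """Per-beat truth aligned with the generated annotations."""

    labels: list[str]
    beat_times_s: np.ndarray       # R times in seconds
    r_samples: np.ndarray
    foot_samples: np.ndarray       # pulse-foot (onset) samples
    peak_samples: np.ndarray       # pulse-apex samples
    pat_s: np.ndarray              # true PAT (R -> pulse foot)
    sbp_mmhg: np.ndarray
    dbp_mmhg: np.ndarray
    sbp_trace: np.ndarray = field(repr=False, default=None)  # at fs

    def __len__(self) -> int:
        return len(self.labels)


def pulse_wave_velocity(sbp_mmhg, config: SyntheticConfig) -> np.ndarray:
    """Moens-Korteweg velocity at the given systolic pressure."""
    e_inc = config.e0_pa * np.exp(config.alpha_per_mmhg * np.asarray(sbp_mmhg))
    return np.sqrt(config.wall_h_m * e_inc / (2 * config.radius_m * config.rho_kg_m3))


def generate_beat_schedule(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    """Beat times and classes.

    A VEB replaces a scheduled sinus beat at ``prematurity * RR`` and
    extends the following interval so that the two flanking intervals sum
    to exactly 2 RR (full compensatory pause).  An SVEB is premature with a
    normally scheduled following interval (non-compensatory).  Ectopics are
    never adjacent.
    """
    mean_rr = 60.0 / config.hr_bpm
    phi, sigma = config.rr_ar1, config.rr_sigma_s
    innov = sigma * np.sqrt(max(1.0 - phi**2, 1e-12))
    times = [1.0]
    labels = ["N"]
    x = 0.0
    pending: float | None = None
    t = 1.0
    while True:
        x = phi * x + innov * rng.standard_normal()
        rr = max(mean_rr + x, 0.3 * mean_rr)
        if pending is not None:
            interval, label = pending, "N"
            pending = None
        else:
            u = rng.random()
            if labels[-1] == "N" and u < config.p_veb + config.p_sveb:
                label = "V" if u < config.p_veb else "S"
                prem = float(np.clip(
                    config.prematurity
                    + config.prematurity_sd * rng.standard_normal(),
                    0.50, 0.90,
                ))
                interval = prem * rr
                if label == "V":
                    pending = (2.0 - prem) * rr
            else:
                label, interval = "N", rr
        t_new = t + interval
        if t_new > config.duration_s - 1.5:
            break
        times.append(t_new)
        labels.append(label)
        t = t_new
    return np.array(times), labels


def _add_noise(x: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    power = float(np.mean((x - np.mean(x)) ** 2))
    if power == 0 or not np.isfinite(snr_db):
        return x
    sigma = np.sqrt(power / 10 ** (snr_db / 10))
    return x + sigma * rng.standard_normal(len(x))


def _wander(n: int, fs: float, amp: float, freq: float,
            rng: np.random.Generator) -> np.ndarray:
    phase = rng.uniform(0, 2 * np.pi)
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


def synthesize_ecg(
    times: np.ndarray,
    labels: list[str],
    config: SyntheticConfig,
    rng: np.random.Generator,
    noise: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """ECG channel as a sum of Gaussian waves + (R-peak samples)."""
    n = int(round(config.duration_s * config.fs))
    fs = config.fs
    ecg = np.zeros(n)
    t_axis = np.arange(n) / fs
    for t_r, label in zip(times, labels):
        for wave, (amp, center, width) in ECG_WAVES.items():
            if label in ("V", "S") and wave == "P":
                continue  # ectopics have no (normal) P wave
            if label == "V":
                if wave in ("Q", "R", "S"):
                    amp *= config.veb_qrs_amp
                    width *= config.veb_qrs_width
                elif wave == "T":
                    # large discordant (inverted) T wave typical of
                    # ventricular beats
                    amp = -0.60
                    width = 0.08
            c = t_r + center
            lo = max(0, int((c - 5 * width) * fs))
            hi = min(n, int((c + 5 * width) * fs) + 1)
            if hi > lo:
                ecg[lo:hi] += amp * np.exp(
                    -((t_axis[lo:hi] - c) ** 2) / (2 * width**2)
                )
    r_samples = np.round(times * fs).astype(int)
    if noise:
        ecg = _add_noise(ecg, config.snr_db, rng)
        ecg += _wander(n, fs, config.wander_amp_ecg, config.wander_hz, rng)
    return ecg, r_samples


def synthesize_bp_pat(
    times: np.ndarray,
    labels: list[str],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """SBP/DBP per beat, true PAT per beat, and the continuous SBP trace.

    PAT_i = L / v(SBP(t_i)) + pre-ejection jitter; ectopic beats eject late
    (reduced contractility), adding ``ectopic_pep_shift_s``.  Monotone
    contract: higher SBP -> shorter PAT.
    """
    n = int(round(config.duration_s * config.fs))
    t_axis = np.arange(n) / config.fs
    ph_d, ph_r = rng.uniform(0, 2 * np.pi, size=2)

    def sbp_of(t):
        return (
            config.sbp_base_mmhg
            + config.sbp_drift_mmhg
            * np.sin(2 * np.pi * t / config.sbp_drift_period_s + ph_d)
            + config.sbp_resp_mmhg * np.sin(2 * np.pi * config.resp_hz * t + ph_r)
        )

    sbp_trace = sbp_of(t_axis)
    sbp_beats = sbp_of(times)
    dbp_beats = sbp_beats - config.pulse_pressure_mmhg
    pat = config.path_l_m / pulse_wave_velocity(sbp_beats, config)
    if config.pep_jitter_s > 0:
        pat = pat + config.pep_jitter_s * rng.standard_normal(len(times))
    ectopic = np.array([l != "N" for l in labels])
    pat = pat + ectopic * (
        config.ectopic_pep_shift_s
        + config.ectopic_pep_jitter_s * rng.standard_normal(len(times))
    )
    return sbp_beats, dbp_beats, pat, sbp_trace


def _pulse_shape(tau: np.ndarray, rise: float, decay_fast: float,
                 decay_slow: float, slow_frac: float,
                 dicrotic_amp: float) -> np.ndarray:
    """Unit pulse: quarter-sine upstroke, two-phase decay, dicrotic bump.

    The upstroke has a non-zero slope at the foot, so the rendered local
    minimum coincides with the template start (the ground-truth foot).  The
    steep post-systolic phase of the decay lets a small premature pulse
    still be the local maximum of its own RR interval.
    """
    d = tau - rise
    y = np.where(
        tau < rise,
        np.sin(0.5 * np.pi * np.clip(tau, 0, None) / rise),
        (1 - slow_frac) * np.exp(-np.clip(d, 0, None) / decay_fast)
        + slow_frac * np.exp(-np.clip(d, 0, None) / decay_slow),
    )
    y = y + dicrotic_amp * np.exp(-((tau - rise - 0.18) ** 2) / (2 * 0.035**2))
    return np.where(tau >= 0, y, 0.0)


def synthesize_ppg(
    times: np.ndarray,
    labels: list[str],
    pat: np.ndarray,
    sbp_beats: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
    noise: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PPG channel + ground-truth (foot samples, peak samples)."""
    n = int(round(config.duration_s * config.fs))
    fs = config.fs
    ppg = np.zeros(n)
    mean_rr = 60.0 / config.hr_bpm

    rr_prec = np.diff(times, prepend=times[0] - mean_rr)
    amps = np.clip(rr_prec / mean_rr, 0.5, 1.6)
    for i, label in enumerate(labels):
        if label != "N":
            # VEB: ineffective ventricular ejection, amplitude fixed at the
            # ectopic factor.  SVEB: normal ventricle, amplitude recovers
            # toward normal as the coupling interval (filling time) grows —
            # late-coupled SVEBs are nearly invisible in the pulse wave.
            ratio = rr_prec[i] / mean_rr
            if label == "V":
                factor = config.ectopic_pulse_amp
            else:
                factor = float(np.clip(
                    config.ectopic_pulse_amp
                    + config.sveb_amp_slope * (ratio - config.prematurity),
                    0.18, 1.0,
                ))
            amps[i] = factor * amps[max(i - 1, 0)]
            if i + 1 < len(amps):
                # post-extrasystolic potentiation grows with prematurity; a
                # late-coupled extrasystole leaves almost no pulse echo
                w = float(np.clip((0.9 - ratio) / 0.3, 0.0, 1.0))
                amps[i + 1] *= 1.0 + (config.post_ectopic_amp - 1.0) * w
    if config.ppg_amp_jitter > 0:
        amps = amps * (1 + config.ppg_amp_jitter * rng.standard_normal(len(amps)))

    foot_times = times + pat
    foot_samples = np.round(foot_times * fs).astype(int)
    peak_samples = np.zeros(len(times), dtype=int)

    widths = 1.0 - config.ppg_width_sbp_coeff * (sbp_beats - 120.0)
    for i, label in enumerate(labels):
        rise = config.ppg_rise_s * widths[i]
        d_fast = config.ppg_decay_fast_s * widths[i]
        d_slow = config.ppg_decay_slow_s * widths[i]
        if label == "V":
            # failed ventricular ejection degrades the pulse to a narrow
            # notch; an SVEB ejects normally and keeps the normal shape
            # (only its amplitude and timing betray it in the pulse wave)
            rise *= 0.55
            d_fast *= 0.55
            d_slow *= 0.55
        lo = foot_samples[i]
        hi = min(n, lo + int(1.8 * fs))
        if lo >= n or hi <= lo:
            continue
        tau = (np.arange(lo, hi) - foot_times[i] * fs) / fs
        ppg[lo:hi] += amps[i] * _pulse_shape(
            tau, rise, d_fast, d_slow, config.ppg_decay_slow_frac,
            config.ppg_dicrotic_amp,
        )
        # ground-truth apex: rendered argmax over the systolic lobe
        span = min(hi, lo + int((rise + 0.08) * fs))
        peak_samples[i] = lo + int(np.argmax(ppg[lo:span])) if span > lo else lo
    if noise:
        ppg = _add_noise(ppg, config.snr_db, rng)
        ppg += _wander(n, fs, config.wander_amp_ppg, config.wander_hz, rng)
    return ppg, foot_samples, peak_samples


def synthesize_abp(
    times: np.ndarray,
    foot_samples: np.ndarray,
    sbp_beats: np.ndarray,
    dbp_beats: np.ndarray,
    config: SyntheticConfig,
) -> np.ndarray:
    """ABP channel whose per-beat max/min equal ground-truth SBP/DBP."""
    n = int(round(config.duration_s * config.fs))
    fs = config.fs
    abp = np.full(n, float(np.mean(dbp_beats)))
    rise = config.ppg_rise_s
    for i in range(len(times)):
        lo = foot_samples[i]
        hi = foot_samples[i + 1] if i + 1 < len(times) else n
        lo, hi = max(0, lo), min(n, hi)
        if hi <= lo:
            continue
        tau = (np.arange(lo, hi) - lo) / fs
        unit = _pulse_shape(
            tau, rise, config.ppg_decay_fast_s, config.ppg_decay_slow_s,
            config.ppg_decay_slow_frac, 0.10,
        )
        unit = unit / max(np.max(unit), 1e-12)
        abp[lo:hi] = dbp_beats[i] + (sbp_beats[i] - dbp_beats[i]) * unit
    if len(foot_samples):
        abp[: max(0, foot_samples[0])] = dbp_beats[0]
    return abp


def generate_record(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[Record, AnnotationSet, GroundTruth]:
    """Fully assembled synchronized record, deterministic under (config, seed)."""
    config = config or SyntheticConfig()
    seed = config.seed if seed is None else seed
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(4)]
    rng_sched, rng_bp, rng_ecg, rng_ppg = streams

    times, labels = generate_beat_schedule(config, rng_sched)
    sbp_b, dbp_b, pat, sbp_trace = synthesize_bp_pat(times, labels, config, rng_bp)
    ecg, r_samples = synthesize_ecg(times, labels, config, rng_ecg)
    ppg, foot_samples, peak_samples = synthesize_ppg(
        times, labels, pat, sbp_b, config, rng_ppg
    )
    abp = synthesize_abp(times, foot_samples, sbp_b, dbp_b, config)

    record = Record(
        subject_id=f"synth-{seed}",
        fs=config.fs,
        channels={"ecg": ecg, "ppg": ppg, "abp": abp},
        units={"ecg": "mV", "ppg": "a.u.", "abp": "mmHg"},
    )
    annotations = AnnotationSet(
        record_id=record.subject_id,
        beats=[BeatAnnotation(int(s), l) for s, l in zip(r_samples, labels)],
    )
    gt = GroundTruth(
        labels=list(labels),
        beat_times_s=times,
        r_samples=r_samples,
        foot_samples=foot_samples,
        peak_samples=peak_samples,
        pat_s=pat,
        sbp_mmhg=sbp_b,
        dbp_mmhg=dbp_b,
        sbp_trace=sbp_trace,
    )
    return record, annotations, gt


def clean_twin_config(config: SyntheticConfig) -> SyntheticConfig:
    """Same conditions with ectopic beats disabled (for clean-reference runs)."""
    return replace(config, p_veb=0.0, p_sveb=0.0)


def generate_cohort(
    n_subjects: int = 10,
    config: SyntheticConfig | None = None,
    seed: int = 7,
    min_ectopics: int = 5,
) -> Iterator[tuple[str, Record, AnnotationSet, GroundTruth]]:
    """Multi-subject cohort with per-subject parameter jitter.

    Subject-level heart rate and baseline pressure vary across subjects;
    the pulse-morphology/pressure coupling is shared (a cohort-level
    property a cross-subject regressor can learn).  Subjects are redrawn
    deterministically until each carries at least ``min_ectopics`` beats of
    both ectopic classes.
    """
    base = config or SyntheticConfig()
    jit_rng = np.random.default_rng(seed)
    for i in range(n_subjects):
        hr = float(jit_rng.uniform(62, 80))
        sbp = float(jit_rng.uniform(108, 132))
        rr_sig = float(jit_rng.uniform(0.018, 0.032))
        attempt = 0
        while True:
            sub_seed = (seed * 1009 + i * 101 + attempt * 13) % (2**31)
            cfg = replace(
                base, hr_bpm=hr, sbp_base_mmhg=sbp, rr_sigma_s=rr_sig,
                seed=sub_seed,
            )
            rec, ann, gt = generate_record(cfg, sub_seed)
            n_s = sum(1 for l in gt.labels if l == "S")
            n_v = sum(1 for l in gt.labels if l == "V")
            if base.p_veb == 0 and base.p_sveb == 0:
                break
            if n_s >= min_ectopics and n_v >= min_ectopics:
                break
            attempt += 1
            if attempt > 20:  # pragma: no cover - defensive
                break
        subject_id = f"S{i:02d}"
        rec.subject_id = subject_id
        yield subject_id, rec, ann, gt
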