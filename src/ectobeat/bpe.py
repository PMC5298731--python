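"""Pulse-arrival-time blood-pressure estimation and its error metrics.

Three estimation routes are implemented:

* **Chen** — first-order PAT tracking around an intermittent cuff
  calibration:  Pe(t) = Pb - (2 / (gamma * Tb)) * dT(t),  with dT the PAT
  change since calibration, Pb/Tb the pressure and PAT at calibration and
  gamma = 0.017 mmHg^-1.  This is the Taylor form implied by the
  exponential elasticity + Moens-Korteweg relations (P depends on PAT
  through (2/gamma) * ln(K/T), whose derivative is -2/(gamma*T)).
* **Cattivelli** — per-target linear model  BP = a*PAT + b*HR + c,
  initially least-squares fitted on Ncal calibration beats (default 40)
  and intermittently recalibrated with recursive least squares (RLS,
  forgetting factor lambda; lambda = 1 reproduces batch least squares on
  all data seen).
* **Kurylyak** — pulse-morphology regression: 21 PPG waveform features
  (systolic/diastolic widths at 10-70 % of the pulse amplitude, upstroke/
  diastolic/period times, diastolic-to-systolic width ratios) feed the
  shared MLP regressor.

Ectopic-beat clearance drops the PAT/feature sample of every beat the
detector flags as ectopic; calibration events falling on a dropped beat
defer to the next retained beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .delineation import DelineatedBeat
from .features import BeatExcluded
from .mlp import SCGNetworkRegressor

GAMMA_PER_MMHG = 0.017

KURYLYAK_LEVELS = (0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70)
KURYLYAK_RATIO_LEVELS = (0.10, 0.30, 0.50, 0.70)
N_KURYLYAK = 21


# ---------------------------------------------------------------------------
# Pulse arrival time
# ---------------------------------------------------------------------------

@dataclass
class PATSample:
    """Per-beat pulse arrival time + instantaneous heart rate."""

    beat_index: int
    pat: float       # seconds, R peak -> PPG fiducial
    hr: float        # bpm, 60 / preceding RR
    valid: bool


def compute_pat(
    beats: list[DelineatedBeat], fs: float, fiducial: str = "onset"
) -> list[PATSample]:
    """PAT per beat from its delineated fiducials.

    ``fiducial`` selects the pulse foot (``onset``, the default used by the
    PAT-based estimators) or the pulse apex (``peak``).  Invalid beats give
    invalid samples.
    """
    if fiducial not in ("onset", "peak"):
        raise ValueError(f"unknown fiducial {fiducial!r}")
    out = []
    for i, b in enumerate(beats):
        idx = b.ppg_onset if fiducial == "onset" else b.ppg_peak
        if not b.valid or idx < 0:
            out.append(PATSample(i, np.nan, np.nan, False))
            continue
        out.append(PATSample(i, (idx - b.r) / fs, 60.0 / b.rr_prec, True))
    return out


# ---------------------------------------------------------------------------
# Chen
# ---------------------------------------------------------------------------

@dataclass
class ChenCalibration:
    """Reference pressure and PAT captured at the last calibration."""

    pb_mmhg: float
    tb_s: float
    gamma: float = GAMMA_PER_MMHG
    time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.tb_s <= 0:
            raise ValueError(f"calibration PAT must be > 0, got {self.tb_s}")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


def chen_estimate(pat_s, calib: ChenCalibration) -> np.ndarray:
    """Pe = Pb - (2 / (gamma * Tb)) * (PAT - Tb); affine in the PAT change."""
    dt = np.asarray(pat_s, dtype=float) - calib.tb_s
    return calib.pb_mmhg - (2.0 / (calib.gamma * calib.tb_s)) * dt


def run_chen(
    pat: np.ndarray,
    times_s: np.ndarray,
    ref_sbp: np.ndarray,
    calib_interval_s: float = 60.0,
    gamma: float = GAMMA_PER_MMHG,
) -> np.ndarray:
    """Chen estimation over a beat series with interval-based recalibration.

    ``pat``/``ref_sbp`` may contain NaN for unavailable beats; those produce
    no estimate, and calibration events falling on them defer to the next
    usable beat.
    """
    pat = np.asarray(pat, dtype=float)
    est = np.full(len(pat), np.nan)
    calib: ChenCalibration | None = None
    next_calib = -np.inf
    for i in range(len(pat)):
        if not np.isfinite(pat[i]) or pat[i] <= 0:
            continue
        if times_s[i] >= next_calib and np.isfinite(ref_sbp[i]):
            calib = ChenCalibration(
                pb_mmhg=float(ref_sbp[i]), tb_s=float(pat[i]),
                gamma=gamma, time_s=float(times_s[i]),
            )
            next_calib = times_s[i] + calib_interval_s
        if calib is not None:
            est[i] = chen_estimate(pat[i], calib)
    return est


# ---------------------------------------------------------------------------
# Cattivelli
# ---------------------------------------------------------------------------

@dataclass
class CalibrationState:
    """Coefficients + RLS inverse covariance for one pressure target."""

    theta: np.ndarray            # (a, b, c) for BP = a*PAT + b*HR + c
    p_matrix: np.ndarray         # 3x3 inverse covariance
    forgetting: float = 0.99
    n_obs: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.forgetting <= 1:
            raise ValueError("forgetting factor must be in (0, 1]")


def cattivelli_fit(
    pat: np.ndarray, hr: np.ndarray, bp_ref: np.ndarray,
    forgetting: float = 0.99,
) -> CalibrationState:
    """Ordinary least squares on [PAT, HR, 1] -> BP, seeding the RLS state."""
    pat = np.asarray(pat, dtype=float)
    hr = np.asarray(hr, dtype=float)
    bp_ref = np.asarray(bp_ref, dtype=float)
    if len(pat) < 3:
        raise ValueError(f"need >= 3 calibration pairs, got {len(pat)}")
    X = np.column_stack([pat, hr, np.ones(len(pat))])
    gram = X.T @ X
    if np.linalg.matrix_rank(gram) < 3:
        raise ValueError("degenerate calibration: PAT/HR design is rank-deficient")
    theta = np.linalg.solve(gram, X.T @ bp_ref)
    return CalibrationState(
        theta=theta, p_matrix=np.linalg.inv(gram),
        forgetting=forgetting, n_obs=len(pat),
    )


def cattivelli_update(
    state: CalibrationState, pat: float, hr: float, bp_ref: float
) -> CalibrationState:
    """Standard RLS update; with forgetting = 1 it reproduces batch LS.

    The inverse covariance is re-symmetrized after the rank-one update to
    keep it numerically positive definite over long runs.
    """
    if not (np.isfinite(pat) and np.isfinite(hr) and np.isfinite(bp_ref)):
        raise ValueError("non-finite RLS inputs")
    x = np.array([pat, hr, 1.0])
    lam = state.forgetting
    P = state.p_matrix
    denom = lam + x @ P @ x
    k = (P @ x) / denom
    innovation = bp_ref - x @ state.theta
    theta = state.theta + k * innovation
    P = (P - np.outer(k, x @ P)) / lam
    P = 0.5 * (P + P.T)
    return CalibrationState(
        theta=theta, p_matrix=P, forgetting=lam, n_obs=state.n_obs + 1
    )


def cattivelli_estimate(state: CalibrationState, pat, hr) -> np.ndarray:
    """Linear evaluation  BP = a*PAT + b*HR + c."""
    pat = np.asarray(pat, dtype=float)
    hr = np.asarray(hr, dtype=float)
    return state.theta[0] * pat + state.theta[1] * hr + state.theta[2]


class CattivelliModel(RegressorMixin, BaseEstimator):
    """PAT+HR linear blood-pressure model with RLS recalibration.

    ``fit`` performs the initial least-squares calibration on
    ``X = [[pat, hr], ...]`` against one pressure target; ``partial_fit``
    applies one RLS recalibration per sample; ``predict`` evaluates the
    current coefficients.
    """

    def __init__(self, forgetting: float = 0.99):
        self.forgetting = forgetting

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.state_ = cattivelli_fit(X[:, 0], X[:, 1], y, self.forgetting)
        self.coef_ = self.state_.theta[:2]
        self.intercept_ = self.state_.theta[2]
        self.n_features_in_ = 2
        return self

    def partial_fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        for xi, yi in zip(X, y):
            self.state_ = cattivelli_update(self.state_, xi[0], xi[1], yi)
        self.coef_ = self.state_.theta[:2]
        self.intercept_ = self.state_.theta[2]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return cattivelli_estimate(self.state_, X[:, 0], X[:, 1])


def run_cattivelli(
    pat: np.ndarray,
    hr: np.ndarray,
    times_s: np.ndarray,
    ref_sbp: np.ndarray,
    n_cal: int = 40,
    calib_interval_s: float = 60.0,
    forgetting: float = 0.99,
) -> np.ndarray:
    """Cattivelli SBP estimation over a beat series.

    The first ``n_cal`` usable beats form the initial calibration (no
    estimates are emitted for them); afterwards one RLS recalibration runs
    per ``calib_interval_s``, deferred past unusable beats.
    """
    pat = np.asarray(pat, dtype=float)
    usable = np.isfinite(pat) & np.isfinite(hr) & (pat > 0)
    est = np.full(len(pat), np.nan)
    cal_idx = np.flatnonzero(usable)[:n_cal]
    if len(cal_idx) < n_cal:
        raise ValueError(f"not enough usable beats for Ncal={n_cal} calibration")
    state = cattivelli_fit(
        pat[cal_idx], hr[cal_idx], ref_sbp[cal_idx], forgetting
    )
    next_calib = times_s[cal_idx[-1]] + calib_interval_s
    for i in range(cal_idx[-1] + 1, len(pat)):
        if not usable[i]:
            continue
        if times_s[i] >= next_calib and np.isfinite(ref_sbp[i]):
            state = cattivelli_update(state, pat[i], hr[i], ref_sbp[i])
            next_calib = times_s[i] + calib_interval_s
        est[i] = float(cattivelli_estimate(state, pat[i], hr[i]))
    return est


# ---------------------------------------------------------------------------
# Kurylyak pulse-morphology features + regressor
# ---------------------------------------------------------------------------

def kurylyak_features(ppg: np.ndarray, beat: DelineatedBeat, fs: float) -> np.ndarray:
    """The 21 pulse-waveform features of one beat, all in seconds (ratios
    dimensionless).

    Order: systolic widths SW_h for h in 10..70 % (7), diastolic widths
    DW_h (7), systolic upstroke time, diastolic time, pulse period, then
    DW_h/SW_h ratios at 10/30/50/70 % (4).  Widths measure the time from
    the upstroke (resp. to the downstroke) crossing of each fractional
    amplitude level to the pulse peak; crossings use linear interpolation.
    A level that is never crossed marks a malformed pulse and excludes the
    beat.
    """
    ppg = np.asarray(ppg, dtype=float)
    if not beat.ppg_complete:
        raise BeatExcluded("missing PPG fiducials")
    o, p, o2 = beat.ppg_onset, beat.ppg_peak, beat.ppg_onset_next
    pulse = ppg[o : o2 + 1]
    k_peak = p - o
    baseline = pulse[0]
    amp = pulse[k_peak] - baseline
    if amp <= 0:
        raise BeatExcluded("pulse-too-flat")

    def up_crossing(level: float) -> float:
        seg = pulse[: k_peak + 1]
        above = np.flatnonzero(seg >= level)
        if len(above) == 0 or above[0] == 0:
            if len(above) and seg[0] >= level:
                return 0.0
            raise BeatExcluded("level never crossed on upstroke")
        j = above[0]
        return (j - 1) + (level - seg[j - 1]) / (seg[j] - seg[j - 1])

    def down_crossing(level: float) -> float:
        seg = pulse[k_peak:]
        below = np.flatnonzero(seg <= level)
        if len(below) == 0:
            raise BeatExcluded("level never crossed on downstroke")
        j = below[0]
        if j == 0:
            return float(k_peak)
        return k_peak + (j - 1) + (seg[j - 1] - level) / (seg[j - 1] - seg[j])

    sw, dw = {}, {}
    for h in KURYLYAK_LEVELS:
        level = baseline + h * amp
        sw[h] = (k_peak - up_crossing(level)) / fs
        dw[h] = (down_crossing(level) - k_peak) / fs

    features = [sw[h] for h in KURYLYAK_LEVELS]
    features += [dw[h] for h in KURYLYAK_LEVELS]
    features += [
        k_peak / fs,                 # systolic upstroke time (onset -> peak)
        (o2 - p) / fs,               # diastolic time (peak -> next onset)
        (o2 - o) / fs,               # pulse period (onset -> next onset)
    ]
    for h in KURYLYAK_RATIO_LEVELS:
        if sw[h] <= 0:
            raise BeatExcluded("degenerate systolic width")
        features.append(dw[h] / sw[h])
    return np.array(features)


def extract_kurylyak_features(
    ppg: np.ndarray, beats: list[DelineatedBeat], fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """(n_beats, 21) feature matrix + indices of retained beats."""
    rows, idx = [], []
    for i, b in enumerate(beats):
        try:
            rows.append(kurylyak_features(ppg, b, fs))
        except BeatExcluded:
            continue
        idx.append(i)
    if not rows:
        return np.empty((0, N_KURYLYAK)), np.array([], dtype=int)
    return np.vstack(rows), np.array(idx, dtype=int)


class KurylyakRegressor(SCGNetworkRegressor):
    """Pulse-morphology SBP/DBP regressor on the shared SCG MLP engine."""

    def __init__(self, hidden_layer_sizes=(15, 10), activation="tanh",
                 max_iter=800, validation_fraction=0.1, patience=15,
                 standardize=True, random_state=0):
        super().__init__(
            hidden_layer_sizes=hidden_layer_sizes, activation=activation,
            max_iter=max_iter, validation_fraction=validation_fraction,
            patience=patience, standardize=standardize,
            random_state=random_state,
        )


def kurylyak_estimate(model: SCGNetworkRegressor, features: np.ndarray) -> np.ndarray:
    """Evaluate a trained pulse-morphology regressor on feature rows."""
    return model.predict(np.atleast_2d(features))


# ---------------------------------------------------------------------------
# Ectopic clearance + error metrics
# ---------------------------------------------------------------------------

def clearance_mask(beat_labels, policy: str = "drop") -> np.ndarray:
    """Boolean mask of retained beats.

    ``labels`` may be class strings (ectopic = anything but "N") or a
    boolean ectopic flag.  ``drop`` removes exactly the flagged beats;
    ``drop_following`` additionally removes the beat after each flagged
    one (its post-extrasystolic pulse is potentiated).
    """
    labels = np.asarray(beat_labels)
    ectopic = labels if labels.dtype == bool else labels != "N"
    keep = ~ectopic
    if policy == "drop_following":
        keep[1:] &= ~ectopic[:-1]
    elif policy != "drop":
        raise ValueError(f"unknown clearance policy {policy!r}")
    return keep


def clear_ectopic(samples, beat_labels, policy: str = "drop"):
    """Filtered copy of a per-beat sample sequence."""
    samples = np.asarray(samples)
    if len(samples) != len(beat_labels):
        raise ValueError(
            f"length mismatch: {len(samples)} samples vs {len(beat_labels)} labels"
        )
    return samples[clearance_mask(beat_labels, policy)]


@dataclass
class BPEMetrics:
    """Beat-wise estimation-error summary (errors e = estimate - reference)."""

    mean_error: float
    sd_error: float        # sample SD (n-1)
    cc: float              # Pearson correlation estimate vs reference
    mse: float
    rmse: float
    ea_mean: float         # mean absolute error
    ea_sd: float
    er_mean: float | None  # mean relative error, % of reference
    er_sd: float | None
    prob_within: dict[float, float] = field(default_factory=dict)
    n: int = 0

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "prob_within"}
        d.update({f"prob_within_{k:g}pct": v for k, v in self.prob_within.items()})
        return d


def bpe_error_metrics(
    est, ref, prob_levels: tuple[float, ...] = (5.0, 10.0, 16.0)
) -> BPEMetrics:
    """Full error-measure suite over aligned estimate/reference series.

    NaN pairs are discarded first; at least 2 pairs must remain.  Relative
    errors are undefined (None) when the reference contains zeros.
    """
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("estimate/reference must be aligned")
    ok = np.isfinite(est) & np.isfinite(ref)
    est, ref = est[ok], ref[ok]
    n = len(est)
    if n < 2:
        raise ValueError(f"need >= 2 paired samples, got {n}")
    e = est - ref
    abs_e = np.abs(e)
    mse = float(np.mean(e**2))
    cc = float(np.corrcoef(est, ref)[0, 1]) if np.std(est) > 0 and np.std(ref) > 0 else 0.0
    if np.any(ref == 0):
        er_mean = er_sd = None
        prob = {}
    else:
        rel = 100.0 * abs_e / np.abs(ref)
        er_mean, er_sd = float(np.mean(rel)), float(np.std(rel, ddof=1))
        prob = {x: float(np.mean(rel <= x)) for x in prob_levels}
    return BPEMetrics(
        mean_error=float(np.mean(e)),
        sd_error=float(np.std(e, ddof=1)),
        cc=cc,
        mse=mse,
        rmse=float(np.sqrt(mse)),
        ea_mean=float(np.mean(abs_e)),
        ea_sd=float(np.std(abs_e, ddof=1)),
        er_mean=er_mean,
        er_sd=er_sd,
        prob_within=prob,
        n=n,
    )
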