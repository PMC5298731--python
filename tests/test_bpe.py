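import numpy as np
import pytest

from ectobeat.bpe import (
    CattivelliModel,
    ChenCalibration,
    bpe_error_metrics,
    cattivelli_estimate,
    cattivelli_fit,
    cattivelli_update,
    chen_estimate,
    clear_ectopic,
    clearance_mask,
    compute_pat,
    kurylyak_features,
    run_chen,
)
from ectobeat.delineation import DelineatedBeat
from ectobeat.features import BeatExcluded


def _beat_with_pulse(r=1000, onset=1125, peak=1175, fs=500.0):
    b = DelineatedBeat(r=r, r_prev=r - 500, r_next=r + 500, rr_prec=1.0,
                       rr_foll=1.0, ppg_onset=onset, ppg_peak=peak,
                       ppg_onset_next=onset + 500, ppg_peak_next=peak + 500,
                       valid=True, ppg_complete=True)
    return b


class TestPat:
    def test_arithmetic(self):
        pats = compute_pat([_beat_with_pulse()], 500.0, fiducial="onset")
        assert pats[0].pat == pytest.approx(0.250)
        assert pats[0].hr == pytest.approx(60.0)

    def test_invalid_beat_propagates(self):
        b = DelineatedBeat(r=100)
        pats = compute_pat([b], 500.0)
        assert not pats[0].valid and np.isnan(pats[0].pat)

    def test_peak_fiducial(self):
        pats = compute_pat([_beat_with_pulse()], 500.0, fiducial="peak")
        assert pats[0].pat == pytest.approx(0.350)


class TestChen:
    def test_identity_at_zero_delta(self):
        calib = ChenCalibration(pb_mmhg=120.0, tb_s=0.250)
        assert chen_estimate(0.250, calib) == pytest.approx(120.0)

    def test_worked_values(self):
        calib = ChenCalibration(pb_mmhg=120.0, tb_s=0.250, gamma=0.017)
        assert chen_estimate(0.255, calib) == pytest.approx(117.647, abs=0.001)
        assert chen_estimate(0.245, calib) == pytest.approx(122.353, abs=0.001)

    def test_affine_slope(self):
        calib = ChenCalibration(pb_mmhg=120.0, tb_s=0.250, gamma=0.017)
        dts = np.array([-0.01, 0.0, 0.01])
        est = chen_estimate(0.250 + dts, calib)
        slopes = np.diff(est) / np.diff(dts)
        np.testing.assert_allclose(slopes, -2.0 / (0.017 * 0.250), rtol=1e-12)

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError):
            ChenCalibration(pb_mmhg=120.0, tb_s=0.0)

    def test_run_chen_recalibrates_and_skips_nan(self):
        times = np.arange(10, dtype=float) * 10
        pat = np.full(10, 0.25)
        pat[3] = np.nan
        ref = np.full(10, 120.0)
        ref[5:] = 130.0
        est = run_chen(pat, times, ref, calib_interval_s=50.0)
        assert np.isnan(est[3])
        assert est[0] == pytest.approx(120.0)
        assert est[5] == pytest.approx(130.0)  # recalibrated at t=50


class TestCattivelli:
    def _make_data(self, n=200, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        pat = 0.25 + 0.02 * rng.standard_normal(n)
        hr = 70 + 8 * rng.standard_normal(n)
        sbp = -100.0 * pat + 0.3 * hr + 135.0 + noise * rng.standard_normal(n)
        return pat, hr, sbp

    def test_exact_recovery_noise_free(self):
        pat, hr, sbp = self._make_data()
        state = cattivelli_fit(pat, hr, sbp)
        np.testing.assert_allclose(state.theta, [-100.0, 0.3, 135.0], rtol=1e-8)

    def test_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            cattivelli_fit([0.2, 0.3], [60, 70], [120, 118])

    def test_duplicate_pairs_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            cattivelli_fit([0.25] * 5, [70.0] * 5, [120.0] * 5)

    def test_rls_lambda_one_equals_batch(self):
        pat, hr, sbp = self._make_data(n=60, noise=2.0, seed=3)
        state = cattivelli_fit(pat[:40], hr[:40], sbp[:40], forgetting=1.0)
        for i in range(40, 50):
            state = cattivelli_update(state, pat[i], hr[i], sbp[i])
        batch = cattivelli_fit(pat[:50], hr[:50], sbp[:50])
        np.testing.assert_allclose(state.theta, batch.theta, rtol=1e-8)

    def test_zero_innovation_leaves_coefficients(self):
        pat, hr, sbp = self._make_data(n=50, seed=1)
        state = cattivelli_fit(pat, hr, sbp)
        pred = float(cattivelli_estimate(state, 0.26, 72.0))
        updated = cattivelli_update(state, 0.26, 72.0, pred)
        np.testing.assert_allclose(updated.theta, state.theta, atol=1e-10)

    def test_inverse_covariance_stays_spd(self):
        rng = np.random.default_rng(4)
        pat, hr, sbp = self._make_data(n=40, noise=2.0, seed=4)
        state = cattivelli_fit(pat, hr, sbp, forgetting=0.99)
        for _ in range(1000):
            state = cattivelli_update(
                state,
                0.25 + 0.02 * rng.standard_normal(),
                70 + 8 * rng.standard_normal(),
                120 + 5 * rng.standard_normal(),
            )
            np.testing.assert_allclose(state.p_matrix, state.p_matrix.T)
            assert np.all(np.linalg.eigvalsh(state.p_matrix) > 0)

    def test_constant_model(self):
        state = cattivelli_fit([0.2, 0.25, 0.3, 0.22], [60, 70, 80, 65],
                               [120.0] * 4)
        est = cattivelli_estimate(state, [0.27, 0.5], [75, 90])
        np.testing.assert_allclose(est, 120.0, atol=1e-8)

    def test_noisy_coefficient_recovery(self):
        pat, hr, sbp = self._make_data(n=500, noise=2.0, seed=7)
        state = cattivelli_fit(pat, hr, sbp)
        true = np.array([-100.0, 0.3, 135.0])
        rel = np.abs((state.theta - true) / true)
        assert np.all(rel < 0.05)

    def test_sklearn_wrapper_round_trip(self):
        pat, hr, sbp = self._make_data(n=100, noise=1.0, seed=2)
        X = np.column_stack([pat, hr])
        model = CattivelliModel().fit(X[:40], sbp[:40])
        model.partial_fit(X[40:50], sbp[40:50])
        pred = model.predict(X[50:])
        assert np.sqrt(np.mean((pred - sbp[50:]) ** 2)) < 5.0
        assert model.get_params() == {"forgetting": 0.99}


def _triangular_pulse_beat(rise_s, fall_s, fs=500.0):
    rise, fall = int(rise_s * fs), int(fall_s * fs)
    sig = np.zeros(4000)
    start = 1000
    sig[start : start + rise] = np.linspace(0, 1, rise, endpoint=False)
    sig[start + rise : start + rise + fall + 1] = np.linspace(1, 0, fall + 1)
    onset_next = start + rise + fall + 200
    sig[onset_next : onset_next + rise] = np.linspace(0, 1, rise, endpoint=False)
    sig[onset_next + rise : onset_next + rise + fall + 1] = np.linspace(1, 0, fall + 1)
    b = DelineatedBeat(r=start - 100, r_prev=start - 600, r_next=onset_next - 100,
                       rr_prec=1.0, rr_foll=1.0, ppg_onset=start,
                       ppg_peak=start + rise, ppg_onset_next=onset_next,
                       ppg_peak_next=onset_next + rise, valid=True,
                       ppg_complete=True)
    return sig, b


class TestKurylyakFeatures:
    def test_symmetric_triangle_widths(self):
        sig, b = _triangular_pulse_beat(0.2, 0.2)
        f = kurylyak_features(sig, b, 500.0)
        sw, dw = f[:7], f[7:14]
        np.testing.assert_allclose(sw, dw, atol=1e-6)
        # SW at 50% of a 0.2 s linear rise is 0.1 s
        assert f[4] == pytest.approx(0.1, abs=1e-6)

    def test_asymmetric_triangle_ratio(self):
        sig, b = _triangular_pulse_beat(0.2, 0.4)
        f = kurylyak_features(sig, b, 500.0)
        # DW_50 / SW_50 ratio; ratios ordered (10, 30, 50, 70)
        assert f[19] == pytest.approx(2.0, abs=1e-5)

    def test_widths_monotone_decreasing_in_level(self):
        sig, b = _triangular_pulse_beat(0.15, 0.3)
        f = kurylyak_features(sig, b, 500.0)
        assert np.all(np.diff(f[:7]) < 0)
        assert np.all(np.diff(f[7:14]) < 0)

    def test_timing_features(self):
        sig, b = _triangular_pulse_beat(0.2, 0.2)
        f = kurylyak_features(sig, b, 500.0)
        assert f[14] == pytest.approx((b.ppg_peak - b.ppg_onset) / 500.0)
        assert f[16] == pytest.approx((b.ppg_onset_next - b.ppg_onset) / 500.0)

    def test_malformed_pulse_excluded(self):
        sig, b = _triangular_pulse_beat(0.2, 0.2)
        with pytest.raises(BeatExcluded):
            kurylyak_features(np.zeros_like(sig), b, 500.0)

    def test_feature_count(self):
        sig, b = _triangular_pulse_beat(0.1, 0.25)
        assert len(kurylyak_features(sig, b, 500.0)) == 21


class TestClearance:
    def test_drop_policy(self):
        kept = clear_ectopic([1.0, 2.0, 3.0], ["N", "V", "N"])
        np.testing.assert_array_equal(kept, [1.0, 3.0])

    def test_all_normal_identity(self):
        kept = clear_ectopic([1, 2, 3], ["N", "N", "N"])
        np.testing.assert_array_equal(kept, [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            clear_ectopic([1, 2], ["N"])

    def test_drop_following_retention_rate(self):
        rng = np.random.default_rng(0)
        labels = np.where(rng.random(10000) < 0.10, "V", "N")
        # forbid adjacent ectopics as the generator does
        for i in range(1, len(labels)):
            if labels[i - 1] == "V":
                labels[i] = "N"
        mask = clearance_mask(labels, policy="drop_following")
        frac_ect = np.mean(labels == "V")
        expected = 1.0 - 2 * frac_ect
        assert np.mean(mask) == pytest.approx(expected, abs=0.01)

    def test_boolean_flags_accepted(self):
        mask = clearance_mask(np.array([False, True, False]))
        np.testing.assert_array_equal(mask, [True, False, True])


class TestErrorMetrics:
    def test_perfect_estimate(self):
        m = bpe_error_metrics([120.0, 118.0, 122.0], [120.0, 118.0, 122.0])
        assert m.mean_error == 0 and m.rmse == 0 and m.ea_mean == 0
        assert m.prob_within[5.0] == 1.0

    def test_hand_arithmetic(self):
        m = bpe_error_metrics([120.0, 118.0], [118.0, 120.0])
        assert m.mean_error == pytest.approx(0.0)
        assert m.mse == pytest.approx(4.0)
        assert m.rmse == pytest.approx(2.0)
        assert m.ea_mean == pytest.approx(2.0)
        assert m.sd_error == pytest.approx(2.828, abs=1e-3)

    def test_rmse_squared_equals_mse(self):
        rng = np.random.default_rng(1)
        m = bpe_error_metrics(120 + rng.standard_normal(50),
                              120 + rng.standard_normal(50))
        assert m.rmse**2 == pytest.approx(m.mse, abs=1e-9)
        assert -1 <= m.cc <= 1

    def test_prob_within_monotone(self):
        rng = np.random.default_rng(2)
        m = bpe_error_metrics(120 + 5 * rng.standard_normal(200),
                              120 + np.zeros(200),
                              prob_levels=(1, 2, 5, 10, 16, 50))
        probs = [m.prob_within[x] for x in (1, 2, 5, 10, 16, 50)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_zero_reference_flags_relative_errors(self):
        m = bpe_error_metrics([1.0, 2.0], [0.0, 2.0])
        assert m.er_mean is None

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            bpe_error_metrics([120.0], [119.0])
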