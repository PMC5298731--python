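import numpy as np
import pytest

from ectobeat.delineation import delineate_record
from ectobeat.synthetic import (
    SyntheticConfig,
    clean_twin_config,
    generate_beat_schedule,
    generate_cohort,
    generate_record,
    pulse_wave_velocity,
    synthesize_bp_pat,
)


class TestConfig:
    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(p_veb=0.3, p_sveb=0.3)
        with pytest.raises(ValueError):
            SyntheticConfig(fs=-1)

    def test_clean_twin_disables_ectopy(self):
        cfg = clean_twin_config(SyntheticConfig())
        assert cfg.p_veb == 0 and cfg.p_sveb == 0


class TestSchedule:
    def test_pure_sinus_rr_statistics(self):
        cfg = SyntheticConfig(duration_s=600, p_veb=0, p_sveb=0)
        times, labels = generate_beat_schedule(cfg, np.random.default_rng(0))
        rr = np.diff(times)
        assert set(labels) == {"N"}
        assert np.mean(rr) == pytest.approx(60 / cfg.hr_bpm, rel=0.02)
        assert np.std(rr) == pytest.approx(cfg.rr_sigma_s, rel=0.25)

    def test_veb_full_compensatory_pause(self):
        # with RR variability off, prec + foll around a VEB is exactly 2 RR
        cfg = SyntheticConfig(duration_s=300, rr_sigma_s=0.0, p_veb=0.08,
                              p_sveb=0.0)
        times, labels = generate_beat_schedule(cfg, np.random.default_rng(1))
        rr_nominal = 60 / cfg.hr_bpm
        n_veb = 0
        for i, l in enumerate(labels):
            if l == "V" and 0 < i < len(labels) - 1:
                pause = times[i + 1] - times[i - 1]
                assert pause == pytest.approx(2 * rr_nominal, abs=1e-3)
                n_veb += 1
        assert n_veb >= 5

    def test_sveb_non_compensatory(self):
        cfg = SyntheticConfig(duration_s=300, rr_sigma_s=0.0, p_veb=0.0,
                              p_sveb=0.08)
        times, labels = generate_beat_schedule(cfg, np.random.default_rng(2))
        rr_nominal = 60 / cfg.hr_bpm
        for i, l in enumerate(labels):
            if l == "S" and 0 < i < len(labels) - 1:
                pause = times[i + 1] - times[i - 1]
                assert pause < 2 * rr_nominal - 1e-6

    def test_no_adjacent_ectopics(self):
        cfg = SyntheticConfig(duration_s=600, p_veb=0.1, p_sveb=0.1)
        _, labels = generate_beat_schedule(cfg, np.random.default_rng(3))
        for a, b in zip(labels, labels[1:]):
            assert not (a != "N" and b != "N")

    def test_veb_count_binomial_range(self):
        cfg = SyntheticConfig(duration_s=300, hr_bpm=72, p_veb=0.05, p_sveb=0.0)
        _, labels = generate_beat_schedule(cfg, np.random.default_rng(4))
        n_veb = labels.count("V")
        assert 10 <= n_veb <= 26  # 18 +- 8


class TestBpPatCoupling:
    def test_alpha_zero_constant_pat(self):
        cfg = SyntheticConfig(alpha_per_mmhg=1e-12, pep_jitter_s=0.0,
                              ectopic_pep_shift_s=0.0, ectopic_pep_jitter_s=0.0)
        times = np.linspace(1, 100, 80)
        labels = ["N"] * 80
        _, _, pat, _ = synthesize_bp_pat(times, labels, cfg,
                                         np.random.default_rng(0))
        assert np.ptp(pat) < 1e-9

    def test_pat_ratio_closed_form(self):
        # +10 mmHg shortens PAT by the factor exp(-alpha*10/2)
        cfg = SyntheticConfig()
        v0 = pulse_wave_velocity(120.0, cfg)
        v1 = pulse_wave_velocity(130.0, cfg)
        assert v0 / v1 == pytest.approx(np.exp(-0.017 * 10 / 2), rel=1e-12)

    def test_default_operating_point(self):
        cfg = SyntheticConfig()
        pat = cfg.path_l_m / pulse_wave_velocity(120.0, cfg)
        assert pat == pytest.approx(0.250, abs=0.002)

    def test_monotone_pat_sbp(self):
        cfg = SyntheticConfig(pep_jitter_s=0.0, ectopic_pep_shift_s=0.0,
                              ectopic_pep_jitter_s=0.0)
        rec, _, gt = generate_record(cfg, seed=6)
        order = np.argsort(gt.sbp_mmhg)
        assert np.all(np.diff(gt.pat_s[order]) <= 1e-12)

    def test_chen_inversion_within_linearization_error(self):
        # inverting the generator's own PAT through the first-order PAT
        # relation recovers SBP within ~1 mmHg for small excursions
        cfg = SyntheticConfig(pep_jitter_s=0.0, ectopic_pep_shift_s=0.0,
                              ectopic_pep_jitter_s=0.0, p_veb=0, p_sveb=0,
                              sbp_drift_mmhg=4.0, sbp_resp_mmhg=1.0)
        rec, _, gt = generate_record(cfg, seed=8)
        tb = gt.pat_s[0]
        pb = gt.sbp_mmhg[0]
        est = pb - (2.0 / (0.017 * tb)) * (gt.pat_s - tb)
        err = est - gt.sbp_mmhg
        assert np.max(np.abs(err)) < 1.0


class TestPpgConstruction:
    def test_ectopic_amplitude_ratio_nominal_coupling(self):
        cfg = SyntheticConfig(rr_sigma_s=0.0, prematurity_sd=0.0,
                              ppg_amp_jitter=0.0, snr_db=np.inf,
                              wander_amp_ppg=0.0, p_veb=0.08, p_sveb=0.0)
        rec, _, gt = generate_record(cfg, seed=10)
        ppg = rec.channel("ppg")
        labels = gt.labels
        checked = 0
        for i, l in enumerate(labels[:-1]):
            if l != "V" or labels[i - 1] != "N":
                continue
            amp_prev = ppg[gt.peak_samples[i - 1]] - ppg[gt.foot_samples[i - 1]]
            amp_ect = ppg[gt.peak_samples[i]] - ppg[gt.foot_samples[i]]
            assert amp_ect / amp_prev == pytest.approx(0.30, abs=0.06)
            checked += 1
        assert checked >= 3

    def test_noise_free_foot_matches_ground_truth(self):
        cfg = SyntheticConfig(snr_db=np.inf, wander_amp_ppg=0.0,
                              wander_amp_ecg=0.0, p_veb=0, p_sveb=0)
        rec, _, gt = generate_record(cfg, seed=11)
        ppg = rec.channel("ppg")
        for foot in gt.foot_samples[1:-1]:
            lo = foot - 25
            local_min = lo + int(np.argmin(ppg[lo : foot + 25]))
            assert abs(local_min - foot) <= 1

    def test_abp_extrema_match_ground_truth(self):
        cfg = SyntheticConfig(p_veb=0, p_sveb=0)
        rec, _, gt = generate_record(cfg, seed=12)
        abp = rec.channel("abp")
        for i in range(1, len(gt) - 2):
            seg = abp[gt.foot_samples[i] : gt.foot_samples[i + 1]]
            assert np.max(seg) == pytest.approx(gt.sbp_mmhg[i], abs=0.5)
            assert np.min(seg) == pytest.approx(gt.dbp_mmhg[i], abs=0.5)

    def test_measured_snr_matches_setting(self):
        cfg = SyntheticConfig(snr_db=20.0, wander_amp_ecg=0.0, wander_amp_ppg=0.0)
        clean_cfg = SyntheticConfig(snr_db=np.inf, wander_amp_ecg=0.0,
                                    wander_amp_ppg=0.0)
        rec, _, _ = generate_record(cfg, seed=13)
        clean, _, _ = generate_record(clean_cfg, seed=13)
        noise = rec.channel("ecg") - clean.channel("ecg")
        p_sig = np.var(clean.channel("ecg"))
        p_noise = np.var(noise)
        snr = 10 * np.log10(p_sig / p_noise)
        assert snr == pytest.approx(20.0, abs=1.0)


class TestRecordAssembly:
    def test_determinism(self):
        cfg = SyntheticConfig(duration_s=30)
        rec1, ann1, _ = generate_record(cfg, seed=14)
        rec2, ann2, _ = generate_record(cfg, seed=14)
        for name in rec1.channels:
            np.testing.assert_array_equal(rec1.channels[name], rec2.channels[name])
        assert ann1.labels == ann2.labels

    def test_annotations_aligned_with_ground_truth(self, short_record):
        rec, ann, gt = short_record
        np.testing.assert_array_equal(ann.samples, gt.r_samples)
        assert ann.labels == gt.labels

    def test_class_priors_within_binomial_ci(self):
        cfg = SyntheticConfig(duration_s=600)
        _, _, gt = generate_record(cfg, seed=15)
        n = len(gt)
        # each ectopic blocks its neighbour, thinning the realized rate
        # relative to the per-draw probability; allow ~4 sigma around the
        # thinned expectation p/(1+2p)
        for cls, p in (("V", 0.05), ("S", 0.05)):
            k = gt.labels.count(cls)
            expected = p / (1 + 2 * (cfg.p_veb + cfg.p_sveb) / 2)
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(k / n - expected) < 4 * se + 0.01

    def test_cohort_minimum_ectopics_and_determinism(self, default_cohort):
        assert len(default_cohort) == 10
        for sid, rec, ann, gt in default_cohort:
            assert gt.labels.count("S") >= 5
            assert gt.labels.count("V") >= 5
        again = list(generate_cohort(2, seed=7))
        np.testing.assert_array_equal(
            again[0][1].channels["ecg"], default_cohort[0][1].channels["ecg"]
        )

    def test_self_consistent_delineation_noise_free(self, clean_record):
        rec, _, gt = clean_record
        beats = delineate_record(rec, smooth=False, onset_method="foot_min")
        n_ok = 0
        for b in beats:
            if not b.valid:
                continue
            j = int(np.argmin(np.abs(gt.r_samples - b.r)))
            assert abs(b.r - gt.r_samples[j]) <= 1
            assert abs(b.ppg_onset - gt.foot_samples[j]) <= 1
            n_ok += 1
        assert n_ok >= len(gt) - 4
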