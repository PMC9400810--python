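import numpy as np
import pytest

from cardioeeg import eeg_power
from cardioeeg.hrv import compute_hf_power, compute_time_domain
from cardioeeg.rpeak import NNSeries, detect_r_peaks
from cardioeeg.synthetic import (
    CONTROL_GROUP,
    RE_GROUP,
    CohortSpec,
    generate_cohort,
    generate_rr_series,
    generate_subject,
    synthesize_ecg,
    synthesize_eeg,
)

FS = 256.0


def nn_of(rr_ms, beats_s):
    return NNSeries(intervals_ms=rr_ms, times_s=beats_s[1:])


class TestRRSeries:
    def test_constant_rate_limit(self):
        spec = CohortSpec(duration_s=600.0, rr_mean_ms=1000.0, rr_lf_amp_ms=0.0,
                          rr_hf_amp_base_ms=0.0, rr_jitter_ms=0.0)
        rr, beats = generate_rr_series(spec, 0.0, np.random.default_rng(0))
        assert beats.size == 600
        assert np.allclose(rr, 1000.0)

    def test_rmssd_matches_direct_formula(self):
        spec = CohortSpec(duration_s=300.0, rr_mean_ms=1000.0, rr_lf_amp_ms=0.0,
                          rr_hf_amp_base_ms=50.0, rr_jitter_ms=0.0,
                          tone_coupling_gain=0.0)
        rr, beats = generate_rr_series(spec, 0.0, np.random.default_rng(0))
        _, rmssd, _ = compute_time_domain(nn_of(rr, beats))
        oracle = float(np.sqrt(np.mean(np.diff(rr) ** 2)))
        assert rmssd == pytest.approx(oracle, rel=1e-12)

    def test_hf_monotone_in_tone(self):
        spec = CohortSpec(duration_s=300.0, rr_jitter_ms=0.0)
        rng = np.random.default_rng(0)
        hf = {}
        for tone in (-1.0, 1.0):
            rr, beats = generate_rr_series(spec, tone, rng)
            hf[tone] = compute_hf_power(nn_of(rr, beats))
        assert hf[1.0] > hf[-1.0]

    def test_out_of_bounds_spec_rejected(self):
        spec = CohortSpec(duration_s=60.0, rr_mean_ms=500.0, rr_lf_amp_ms=150.0,
                          rr_hf_amp_base_ms=100.0, rr_jitter_ms=0.0,
                          tone_coupling_gain=0.0)
        with pytest.raises(ValueError, match="outside"):
            generate_rr_series(spec, 0.0, np.random.default_rng(0))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(rr_mean_ms=100.0)
        with pytest.raises(ValueError):
            CohortSpec(duration_s=10.3, fs=256.0)


class TestECG:
    def test_single_beat_argmax(self):
        rec, peaks = synthesize_ecg(np.array([1.0]), FS, 3.0,
                                    np.random.default_rng(0),
                                    noise_sd_mv=0.0, wander_mv=0.0)
        assert abs(int(np.argmax(rec.samples[0])) - round(1.0 * FS)) <= 1
        assert peaks.tolist() == [round(1.0 * FS)]

    def test_beat_count_by_threshold(self):
        beats = 0.5 + np.arange(600)
        rec, _ = synthesize_ecg(beats, FS, 600.5, np.random.default_rng(0),
                                noise_sd_mv=0.0, wander_mv=0.0)
        x = rec.samples[0]
        # local maxima above half the R amplitude
        above = (x[1:-1] > 0.5) & (x[1:-1] >= x[:-2]) & (x[1:-1] > x[2:])
        assert int(above.sum()) == 600

    def test_detector_round_trip(self):
        spec = CohortSpec(duration_s=300.0)
        rng = np.random.default_rng(5)
        _, beats = generate_rr_series(spec, 0.3, rng)
        rec, true_peaks = synthesize_ecg(beats, FS, 300.0, rng,
                                         noise_sd_mv=0.0, wander_mv=0.0)
        det = detect_r_peaks(rec)
        hits = sum(
            1 for p in true_peaks if np.min(np.abs(det.peak_indices - p)) <= 2
        )
        assert hits / true_peaks.size >= 0.99

    def test_overlapping_templates_rejected(self):
        with pytest.raises(ValueError, match="300 ms"):
            synthesize_ecg(np.array([1.0, 1.2]), FS, 3.0,
                           np.random.default_rng(0))


class TestEEG:
    def test_band_power_calibration(self, clean_spec):
        """All slopes 0, artifacts off, alpha-1 only at P0 dB."""
        spec = clean_spec
        spec.band_base_db = {"alpha1": 10.0, "delta": -100.0, "theta": -100.0,
                             "alpha2": -100.0, "beta": -100.0}
        spec.band_coupling_slope = {RE_GROUP: 0.0, CONTROL_GROUP: 0.0}
        rng = np.random.default_rng(1)
        eeg, truth = synthesize_eeg(spec, 0.5, RE_GROUP, np.array([], dtype=int),
                                    np.zeros(int(spec.duration_s * FS)), rng)
        table = eeg_power.band_roi_power(eeg)
        merged = table.merge(truth, on=["band", "roi", "hemisphere"],
                             suffixes=("_est", "_true"))
        alpha = merged[merged["band"] == "alpha1"]
        assert np.all(np.abs(alpha["power_db_est"] - 10.0) <= 1.0)
        # other bands see only Welch-window sidelobe leakage from alpha-1,
        # well below the calibrated band
        others = merged[merged["band"] != "alpha1"]
        assert np.all(others["power_db_est"] < 0.0)
        assert np.all(merged[merged["band"].isin(["delta", "beta"])]
                      ["power_db_est"] < -30.0)

    def test_hep_injection_recovered_by_averaging(self):
        """5 µV half-sine at 400-500 ms, 600 beats, 10 µV noise: amplitude
        recovered within 3*sigma/sqrt(N) (sqrt-N averaging law)."""
        spec = CohortSpec(
            duration_s=600.0, rr_mean_ms=1000.0, rr_lf_amp_ms=0.0,
            rr_hf_amp_base_ms=0.0, rr_jitter_ms=0.0, cfa_gain=0.0,
            noise_sd_uv=10.0, hep_amp_uv={RE_GROUP: 5.0},
            hep_topography={c: 1.0 for c in
                            ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3",
                             "C3", "Cz", "C4", "T4", "T5", "P3", "Pz", "P4",
                             "T6", "O1", "O2")},
        )
        rng = np.random.default_rng(2)
        _, beats = generate_rr_series(spec, 0.0, rng)
        peaks = np.round(beats * FS).astype(int)
        eeg, _ = synthesize_eeg(spec, 0.0, RE_GROUP, peaks,
                                np.zeros(int(600 * FS)), rng)
        # average epochs time-locked to the true peaks, no filtering
        ci = eeg.labels.index("Cz")
        lo, hi = int(round(0.4 * FS)), int(round(0.5 * FS))
        n_wave = hi - lo
        template = np.sin(np.pi * (np.arange(n_wave) + 0.5) / n_wave)
        usable = [p for p in peaks if p + hi <= eeg.n_times]
        segs = np.stack([eeg.samples[ci, p + lo: p + hi] for p in usable])
        avg = segs.mean(axis=0)
        amp_hat = float(avg @ template / (template @ template))
        assert abs(amp_hat - 5.0) <= 3 * 10.0 / np.sqrt(len(usable))

    def test_hep_linearity(self):
        """Doubling hep_amp doubles the recovered TOI amplitude."""
        amps = {}
        for amp in (3.0, 6.0):
            spec = CohortSpec(duration_s=120.0, rr_jitter_ms=0.0, cfa_gain=0.0,
                              noise_sd_uv=0.0, hep_amp_uv={RE_GROUP: amp},
                              hep_topography={"Cz": 1.0},
                              band_base_db={b: -100.0 for b in
                                            ("delta", "theta", "alpha1",
                                             "alpha2", "beta")})
            rng = np.random.default_rng(3)
            _, beats = generate_rr_series(spec, 0.0, rng)
            peaks = np.round(beats * FS).astype(int)
            eeg, _ = synthesize_eeg(spec, 0.0, RE_GROUP, peaks,
                                    np.zeros(int(120 * FS)), rng)
            ci = eeg.labels.index("Cz")
            lo, hi = int(round(0.4 * FS)), int(round(0.5 * FS))
            usable = [p for p in peaks if p + hi <= eeg.n_times]
            segs = np.stack([eeg.samples[ci, p + lo: p + hi] for p in usable])
            amps[amp] = segs.mean(axis=0).mean()
        assert amps[6.0] == pytest.approx(2 * amps[3.0], rel=0.05)

    def test_unknown_channel_in_topography_ignored(self, clean_spec):
        rng = np.random.default_rng(0)
        eeg, truth = synthesize_eeg(clean_spec, 0.0, RE_GROUP,
                                    np.array([], dtype=int),
                                    np.zeros(int(clean_spec.duration_s * FS)), rng)
        assert eeg.n_channels == 19
        assert np.all(np.isfinite(truth["power_db"]))


class TestCohort:
    def test_determinism(self, clean_spec):
        subs1, man1 = generate_cohort(clean_spec)
        subs2, man2 = generate_cohort(clean_spec)
        assert man1 == man2
        for a, b in zip(subs1, subs2):
            assert np.array_equal(a.recording.samples, b.recording.samples)

    def test_counts_and_files(self, tmp_path, clean_spec):
        clean_spec.n_per_group = (3, 2)
        subs, manifest = generate_cohort(clean_spec, tmp_path)
        assert len(subs) == 5
        assert len(list(tmp_path.glob("*.edf"))) == 5
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "true_band_power.csv").exists()
        groups = [s.group_label for s in subs]
        assert groups.count(RE_GROUP) == 3
        assert groups.count(CONTROL_GROUP) == 2

    def test_ground_truth_hrv_round_trip(self, default_short_spec):
        """Detected-RMSSD vs generator ground truth: <=5% median rel. error."""
        subs, _ = generate_cohort(default_short_spec)
        errs = []
        for s in subs:
            ecg = s.recording.pick(["ECG"])
            from cardioeeg.rpeak import to_nn_series

            nn = to_nn_series(detect_r_peaks(ecg))
            _, rmssd, _ = compute_time_domain(nn)
            errs.append(abs(rmssd - s.true_hrv["rmssd_ms"]) / s.true_hrv["rmssd_ms"])
        assert np.median(errs) <= 0.05

    def test_subject_invariants(self, clean_spec):
        s = generate_subject(clean_spec, "s1", RE_GROUP, 99)
        assert np.all(np.diff(s.true_r_peaks) > 0)
        assert s.true_r_peaks[0] >= 0
        assert s.true_r_peaks[-1] < s.recording.n_times
        assert np.all(np.isfinite(s.true_band_power_db["power_db"]))
        assert all(np.isfinite(v) for v in s.true_hrv.values())
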