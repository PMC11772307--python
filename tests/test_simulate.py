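"""The synthetic-deployment generators and their ground truth."""

import numpy as np
import pytest

import turtlehr as t
from turtlehr.exceptions import GenerationError, ValidationError
from turtlehr.simulate import read_ground_truth, write_ground_truth


class TestStatusSequence:
    def test_deterministic_under_seed(self):
        bm = t.BehaviorModel(duration_min=500)
        a = t.simulate_status_sequence(bm, seed=9)
        b = t.simulate_status_sequence(bm, seed=9)
        assert np.array_equal(a, b)
        assert len(a) == 500

    def test_infinite_dwell_pins_state(self):
        bm = t.BehaviorModel(moving_dwell_min=np.inf, initial_state=t.MOVING,
                             duration_min=100)
        assert np.all(t.simulate_status_sequence(bm, seed=1) == t.MOVING)

    def test_long_run_resting_fraction(self):
        # Alternating renewal with geometric dwells (means 20 and 10 min):
        # long-run resting fraction is 20/30 = 2/3.  Delta-method s.e. of the
        # ratio-of-sums estimator over ~10000/30 cycles with geometric dwell
        # variances m(m-1) gives sd(f) ~ 0.017, so 3 s.e. ~ 0.05.
        bm = t.BehaviorModel(resting_dwell_min=20, moving_dwell_min=10,
                             duration_min=10_000)
        f = float(np.mean(t.simulate_status_sequence(bm, seed=3) == t.RESTING))
        assert abs(f - 2 / 3) < 0.05

    def test_dwell_below_one_minute_rejected(self):
        with pytest.raises(ValidationError):
            t.BehaviorModel(resting_dwell_min=0.5)


class TestECGGenerator:
    def test_zero_cv_gives_exact_spacing(self):
        statuses = np.array([t.RESTING] * 10)
        cm = t.CardiacModel(resting_hr_bpm=10, moving_hr_bpm=10, rr_cv=0.0)
        ecg, r_times = t.simulate_rr_and_ecg(statuses, cm, t.NoiseModel.none(),
                                             rate=250, seed=0)
        assert np.allclose(np.diff(r_times), 6.0, atol=1e-9)

    def test_noiseless_signal_is_template_train(self):
        statuses = np.array([t.RESTING] * 10)
        cm = t.CardiacModel()
        ecg, r_times = t.simulate_rr_and_ecg(statuses, cm, t.NoiseModel.none(),
                                             rate=250, seed=0)
        # peak of the rendered train equals the R amplitude (to sample-grid
        # resolution), and every beat is a distinct local maximum above A/2
        assert np.abs(ecg.values).max() == pytest.approx(cm.r_amplitude, rel=0.02)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(ecg.values, height=cm.r_amplitude / 2)
        assert peaks.size == r_times.size

    def test_event_rate_matches_configured_hr(self):
        # 24 h all-resting at 8.6 beats/min: the count over 1440 minutes is a
        # sum of ~12000 RR renewals, so the empirical rate is within 2%.
        statuses = np.array([t.RESTING] * 1440)
        _, r_times = t.simulate_rr_and_ecg(statuses, t.CardiacModel(),
                                           t.NoiseModel.none(), rate=250, seed=5)
        assert len(r_times) / 1440 == pytest.approx(8.6, rel=0.02)

    def test_emg_bursts_only_in_moving_minutes(self):
        statuses = np.array([t.RESTING] * 5 + [t.MOVING] * 5 + [t.RESTING] * 5)
        cm = t.CardiacModel()
        quiet, r1 = t.simulate_rr_and_ecg(statuses, cm, t.NoiseModel.none(),
                                          rate=250, seed=7)
        noisy, r2 = t.simulate_rr_and_ecg(
            statuses, cm,
            t.NoiseModel(white_sd=0, wander_amplitude=0, emg_sd=0.05,
                         emg_bursts_per_min=10),
            rate=250, seed=7,
        )
        # same seed => same event train; the difference is exactly the EMG field
        assert np.array_equal(r1, r2)
        diff_minutes = np.unique(
            np.flatnonzero(noisy.values != quiet.values) // (60 * 250)
        )
        assert np.all(statuses[diff_minutes] == t.MOVING)

    def test_low_rate_rejected(self):
        with pytest.raises(ValidationError):
            t.simulate_rr_and_ecg(np.array([t.RESTING]), t.CardiacModel(),
                                  t.NoiseModel.none(), rate=50, seed=0)

    def test_template_wider_than_rr_rejected(self):
        with pytest.raises(GenerationError):
            t.CardiacModel(resting_hr_bpm=600, moving_hr_bpm=600,
                           template_width_s=0.12)


class TestAccelGenerator:
    def test_minute_sd_straddles_threshold_at_defaults(self):
        statuses = np.array([t.RESTING] * 10 + [t.MOVING] * 10)
        accel = t.simulate_accel(statuses, seed=2)
        sds = t.minute_sd(accel).values
        assert np.all(sds[:10] < 0.5)
        assert np.all(sds[10:] > 0.5)

    def test_all_zero_when_silent(self):
        statuses = np.array([t.RESTING, t.MOVING])
        accel = t.simulate_accel(statuses, stroke_amplitude=0.0,
                                 resting_noise_sd=0.0, seed=0)
        assert np.all(accel.values == 0)
        assert np.all(t.minute_sd(accel).values == 0)

    def test_pure_sinusoid_closed_form(self):
        # full-minute sinusoid of amplitude A has SD A/sqrt(2)
        statuses = np.array([t.MOVING] * 3)
        accel = t.simulate_accel(statuses, stroke_amplitude=0.8,
                                 resting_noise_sd=0.0, rate=50, seed=0)
        assert np.allclose(t.minute_sd(accel).values, 0.8 / np.sqrt(2), rtol=0.01)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValidationError):
            t.simulate_accel(np.array([t.RESTING]), stroke_amplitude=-1, seed=0)


class TestGenerateDeployment:
    def test_channel_lengths(self):
        rec, truth = t.generate_deployment(t.BehaviorModel(duration_min=60), seed=1)
        assert rec.ecg.n == 3600 * 250
        assert rec.accel.n == 3600 * 16
        assert len(truth.statuses) == 60
        assert truth.seed == 1 and truth.params["cardiac"]["resting_hr_bpm"] == 8.6

    def test_byte_identical_regeneration(self, tmp_path):
        for d in ("a", "b"):
            rec, _ = t.generate_deployment(t.BehaviorModel(duration_min=3), seed=77)
            t.save_deployment(rec, tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_ground_truth_write_read_round_trip(self, tmp_path):
        _, truth = t.generate_deployment(t.BehaviorModel(duration_min=5), seed=4)
        write_ground_truth(truth, tmp_path)
        back = read_ground_truth(tmp_path)
        assert np.array_equal(back.r_times, truth.r_times)
        assert np.array_equal(back.statuses, truth.statuses)
        assert back.seed == truth.seed
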