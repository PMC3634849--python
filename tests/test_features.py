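"""Line-length features, spectrogram, cumulative curves and onset detection."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seizdyn import features, io_eeg, synthetic_data as sd
from seizdyn.errors import DegenerateSignalError, ParameterError, PreconditionError

from conftest import make_recording


class TestLineLength:
    def test_matches_brute_force_sum(self, rng):
        for _ in range(20):
            x = rng.normal(0, 100, rng.integers(2, 400))
            brute = sum(abs(x[k] - x[k - 1]) for k in range(1, len(x)))
            assert features.line_length(x) == pytest.approx(brute)

    def test_constant_window_is_zero(self):
        assert features.line_length(np.full(100, 7.5)) == 0.0

    def test_alternating_example(self):
        assert features.line_length(np.array([0.0, 1.0, 0.0, 1.0])) == 3.0

    def test_full_period_sine_is_four_amplitudes(self):
        # one period of a finely sampled sine has path length ~ 4A
        fs, f, A = 512.0, 10.0, 250.0
        t = np.arange(int(fs / f)) / fs
        x = A * np.sin(2 * np.pi * f * np.append(t, 1.0 / f))
        assert features.line_length(x) == pytest.approx(4 * A, rel=0.01)

    def test_too_short_window_rejected(self):
        with pytest.raises(PreconditionError):
            features.line_length(np.array([1.0]))


class TestWindowedLineLength:
    def test_window_arithmetic_30s_gives_19_windows(self, rng):
        rec = make_recording(rng.normal(0, 1, (1, int(30 * 512))), fs=512.0)
        out = features.windowed_line_length(rec, "ch0")
        assert len(out.values) == 19
        np.testing.assert_allclose(out.starts, np.arange(0, 28.5, 1.5))
        np.testing.assert_allclose(np.diff(out.times), 1.5)

    def test_constant_signal_gives_zeros(self):
        rec = make_recording(np.full((1, int(30 * 512)), 3.0), fs=512.0)
        assert np.all(features.windowed_line_length(rec, "ch0").values == 0)

    def test_amplitude_step_separates_windows(self, rng):
        x = rng.normal(0, 10, int(30 * 512))
        x[int(15 * 512):] *= 8.0
        rec = make_recording(x, fs=512.0)
        out = features.windowed_line_length(rec, "ch0")
        before = out.values[out.starts + 3.0 <= 15.0]
        after = out.values[out.starts >= 15.0]
        assert after.min() > before.max()

    def test_windows_match_direct_line_length(self, rng):
        # cumulative-sum shortcut equals windowwise brute computation
        x = rng.normal(0, 50, int(12 * 512))
        rec = make_recording(x, fs=512.0)
        out = features.windowed_line_length(rec, "ch0")
        for k in (0, 3, len(out.values) - 1):
            s = int(out.starts[k] * 512)
            assert out.values[k] == pytest.approx(
                features.line_length(x[s : s + int(3 * 512)])
            )

    def test_short_recording_rejected(self, rng):
        rec = make_recording(rng.normal(0, 1, (1, 512)), fs=512.0)
        with pytest.raises(PreconditionError):
            features.windowed_line_length(rec, "ch0")


class TestSpectrogram:
    def test_single_tone_peaks_at_its_frequency(self, sine_recording):
        spec = features.spectrogram(sine_recording(freq=10.0), "a")
        peak = spec.freqs[np.argmax(spec.power, axis=0)]
        assert np.all(peak == 10.0)

    def test_zero_signal_zero_power(self):
        rec = make_recording(np.zeros((1, int(30 * 512))), fs=512.0)
        assert np.all(features.spectrogram(rec, "ch0").power == 0)

    def test_two_tone_power_ratio_near_unity(self):
        fs = 512.0
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 40 * t)
        spec = features.spectrogram(make_recording(x, fs=fs), "ch0")
        i10 = np.argmin(np.abs(spec.freqs - 10))
        i40 = np.argmin(np.abs(spec.freqs - 40))
        ratio = spec.power[i10, 3:-3] / spec.power[i40, 3:-3]
        assert np.all(np.abs(ratio - 1) < 0.1)

    def test_missing_channel_is_lookup_error(self, sine_recording):
        with pytest.raises(KeyError):
            features.spectrogram(sine_recording(), "nope")


class TestCumulativeLineLength:
    def test_monotone_zero_to_one(self, rng):
        x = rng.normal(0, 50, int(120 * 512))
        rec = make_recording(x, fs=512.0)
        curve = features.cumulative_line_length(rec, "ch0", 0.0, duration_s=100.0)
        assert curve.values[0] == 0.0
        assert curve.values[-1] == 1.0
        assert np.all(np.diff(curve.values) >= -1e-12)

    def test_constant_increment_ramp_is_diagonal(self):
        # x[k] = k gives equal increments, hence the straight line t/T
        x = np.arange(int(101 * 512), dtype=float)
        rec = make_recording(x, fs=512.0)
        curve = features.cumulative_line_length(rec, "ch0", 0.0, duration_s=100.0)
        assert np.max(np.abs(curve.values - curve.times / 100.0)) < 1e-6

    def test_flat_second_half_saturates_at_midpoint(self, rng):
        fs = 512.0
        x = np.concatenate(
            [rng.normal(0, 50, int(50 * fs)), np.zeros(int(50 * fs) + 1)]
        )
        rec = make_recording(x, fs=fs)
        curve = features.cumulative_line_length(rec, "ch0", 0.0, duration_s=100.0)
        mid = np.searchsorted(curve.times, 50.0)
        assert curve.values[mid] == pytest.approx(1.0, abs=1e-6)
        assert np.all(curve.values[mid:] == pytest.approx(1.0, abs=1e-9))

    def test_flat_signal_is_degenerate(self):
        rec = make_recording(np.full((1, int(40 * 512)), 5.0), fs=512.0)
        with pytest.raises(DegenerateSignalError):
            features.cumulative_line_length(rec, "ch0", 0.0, duration_s=30.0)

    def test_truncated_curve_is_flagged_and_still_reaches_one(self, rng):
        rec = make_recording(rng.normal(0, 50, int(60 * 512)), fs=512.0)
        curve = features.cumulative_line_length(rec, "ch0", 0.0, duration_s=100.0)
        assert curve.truncated
        assert curve.values[-1] == 1.0

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(scale=st.floats(0.01, 1000.0), seed=st.integers(0, 2**20))
    def test_amplitude_scale_invariance(self, scale, seed):
        x = np.random.default_rng(seed).normal(0, 50, int(30 * 512))
        rec1 = make_recording(x, fs=512.0)
        rec2 = make_recording(scale * x, fs=512.0)
        c1 = features.cumulative_line_length(rec1, "ch0", 0.0, duration_s=25.0)
        c2 = features.cumulative_line_length(rec2, "ch0", 0.0, duration_s=25.0)
        np.testing.assert_allclose(c1.values, c2.values, atol=1e-10)


class TestDetectOnset:
    def _noise_rec(self, rng, dur=600.0, inj=300.0):
        x = rng.normal(0, 50, int(dur * 512))
        return make_recording(x, fs=512.0, events=((inj, "pilocarpine"),))

    def test_pure_noise_has_no_onset(self, rng):
        assert features.detect_onset(self._noise_rec(rng), "ch0") is None

    def test_zero_threshold_fires_at_first_window(self, rng):
        # seizure-scale amplitude everywhere post-injection + degenerate k_sd
        x = rng.normal(0, 50, int(600 * 512))
        x[int(300 * 512):] *= 20.0
        rec = make_recording(x, fs=512.0, events=((300.0, "pilocarpine"),))
        assert features.detect_onset(rec, "ch0", k_sd=0.0) == pytest.approx(0.0, abs=1.5)

    def test_insufficient_baseline_rejected(self, rng):
        rec = self._noise_rec(rng, dur=300.0, inj=60.0)
        with pytest.raises(PreconditionError):
            features.detect_onset(rec, "ch0")

    def test_recovers_programmed_onset_within_30s(self):
        # median error over simulated control animals must stay under 30 s
        cfg = dataclasses.replace(
            sd.default_cohorts(seed=202)[0], post_onset_min=2.0
        )
        errors = []
        for i in range(50):
            rec, _, prof = sd.generate_subject(cfg, i)
            rec = io_eeg.relative_time(io_eeg.standardize(rec))
            det = features.detect_onset(rec, "hippocampal_1")
            assert det is not None
            errors.append(abs(det - prof.onset_s))
        assert np.median(errors) < 30.0
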