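"""Tests of envelope extraction and double-threshold onset detection,
anchored to brute-force window computations and generator ground truth."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pcgnet.preprocess import Recording
from pcgnet.segmentation import (EnvelopeParams, EnvelopeTrace, FrameSet,
                                 SegmentationWarning, detect_s1_onsets,
                                 detect_s2_onsets, double_threshold_onsets,
                                 extract_envelope, extract_frames, moving_mean,
                                 shannon_normalize, time_scale, viola_envelope)
from pcgnet.synthetic import HeartCycleParams, synth_recording


def brute_moving_mean(x, L):
    return np.array([x[m - L:m + L + 1].mean() for m in range(L, len(x) - L)])


def brute_viola(x, L):
    out = []
    for m in range(L, len(x) - L):
        win = x[m - L:m + L + 1]
        out.append(np.mean((win - win.mean()) ** 2))
    return np.array(out)


class TestTimeScale:
    @pytest.mark.parametrize("s,fs,expected", [
        (0.02, 2000.0, 20), (0.01, 2000.0, 10), (0.02, 4000.0, 40),
    ])
    def test_half_window_values(self, s, fs, expected):
        assert time_scale(s, fs) == expected

    def test_sub_sample_scale_rejected(self):
        with pytest.raises(ValueError):
            time_scale(0.001, 100.0)


class TestMovingMean:
    def test_constant_signal(self):
        out = moving_mean(np.full(100, 3.5), 10)
        np.testing.assert_allclose(out, 3.5)
        assert out.size == 100 - 20

    def test_single_impulse(self):
        x = np.zeros(21)
        x[10] = 1.0
        out = moving_mean(x, 2)
        expected = np.zeros(17)
        expected[6:11] = 1 / 5  # windows covering the impulse
        np.testing.assert_allclose(out, expected)

    @given(seed=st.integers(0, 2**16), L=st.sampled_from([2, 7, 20]))
    def test_matches_brute_force(self, seed, L):
        x = np.random.default_rng(seed).standard_normal(200)
        np.testing.assert_allclose(moving_mean(x, L), brute_moving_mean(x, L),
                                   atol=1e-12)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            moving_mean(np.ones(10), 10)


class TestViolaEnvelope:
    def test_constant_signal_zero_envelope(self):
        env = viola_envelope(np.full(200, 2.0), 20)
        assert np.all(env.values == 0.0)

    def test_quadratic_amplitude_scaling(self, rng):
        x = rng.standard_normal(300)
        e1 = viola_envelope(x, 15).values
        e2 = viola_envelope(3.0 * x, 15).values
        np.testing.assert_allclose(e2, 9.0 * e1, rtol=1e-9, atol=1e-12)

    @given(seed=st.integers(0, 2**16), L=st.sampled_from([5, 20, 50]))
    def test_matches_brute_force(self, seed, L):
        x = np.random.default_rng(seed).standard_normal(400)
        env = viola_envelope(x, L)
        np.testing.assert_allclose(env.valid_values, brute_viola(x, L), atol=1e-10)
        # boundary samples are zero-filled on the original timeline
        assert env.values.size == 400
        assert np.all(env.values[:L] == 0) and np.all(env.values[-L:] == 0)

    def test_nonnegative_everywhere(self, rng):
        x = rng.standard_normal(500) * 1e-8  # cancellation-prone scale
        assert np.all(viola_envelope(x, 20).values >= 0)


class TestShannonNormalize:
    def test_constant_positive_envelope_constant_output(self):
        values = np.zeros(200)
        values[20:180] = 0.7
        out = shannon_normalize(EnvelopeTrace(values=values, L_T=20))
        mid = out.values[60:140]  # away from the smoothing edges
        assert np.allclose(mid, mid[0])

    def test_unit_value_maps_to_zero_energy(self):
        # -v^2 log v^2 at v=1 is exactly 0
        assert -(1.0 ** 2) * np.log(1.0 ** 2) == 0.0

    def test_two_lobes_preserved(self):
        t = np.arange(1000)
        values = np.exp(-0.5 * ((t - 300) / 30) ** 2) + 0.4 * np.exp(
            -0.5 * ((t - 700) / 30) ** 2)
        values[:20] = values[-20:] = 0
        env = EnvelopeTrace(values=values, L_T=20)
        out = shannon_normalize(env).values

        def lobe_count(v, thresh=0.05):
            above = v > thresh * v.max()
            return int(np.sum(np.diff(above.astype(int)) == 1))

        assert lobe_count(out) == lobe_count(values) == 2

    def test_all_zero_envelope_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            shannon_normalize(EnvelopeTrace(values=np.zeros(100), L_T=10))


class TestDoubleThreshold:
    def params(self, **kw):
        return EnvelopeParams(**kw)

    def test_flat_zero_envelope_empty_with_warning(self):
        env = EnvelopeTrace(values=np.zeros(500), L_T=20)
        with pytest.warns(SegmentationWarning):
            onsets = double_threshold_onsets(env, self.params())
        assert len(onsets) == 0

    def test_single_bump_single_onset_at_low_crossing(self):
        values = np.zeros(2000)
        t = np.arange(2000)
        values[:] = 1e-6
        bump = np.exp(-0.5 * ((t - 1000) / 40.0) ** 2)
        values += bump
        env = EnvelopeTrace(values=values, L_T=20)
        onsets = double_threshold_onsets(env, self.params())
        assert len(onsets) == 1
        # onset = first index above L on the bump's rise
        expected = np.flatnonzero(values > onsets.L)[0]
        assert onsets.s1_onsets[0] == expected
        assert onsets.s1_onsets[0] < 1000

    def test_recovers_known_s1_onsets(self):
        params = HeartCycleParams(heart_rate=240.0, jitter_sd=0.0)
        rec, truth = synth_recording(params, duration=5.0, fs=2000.0,
                                     snr_db=25.0, rng_seed=5)
        ep = self.params()
        onsets = detect_s1_onsets(rec, ep)
        assert len(onsets) == len(truth.s1_onsets) == 20
        assert np.all(np.abs(onsets.s1_onsets - truth.s1_onsets) <= ep.L_T)

    def test_onsets_invariant_to_amplitude_scaling(self):
        params = HeartCycleParams(heart_rate=220.0)
        rec, _ = synth_recording(params, duration=4.0, snr_db=20.0, rng_seed=9)
        ep = self.params()
        o1 = detect_s1_onsets(rec, ep).s1_onsets
        scaled = Recording(samples=rec.samples * 37.5, fs=rec.fs)
        o2 = detect_s1_onsets(scaled, ep).s1_onsets
        np.testing.assert_array_equal(o1, o2)

    def test_jitter_free_interval_recovery(self):
        params = HeartCycleParams(heart_rate=200.0, jitter_sd=0.0)
        rec, _ = synth_recording(params, duration=4.0, snr_db=25.0, rng_seed=2)
        ep = self.params()
        onsets = detect_s1_onsets(rec, ep).s1_onsets
        intervals = np.diff(onsets)
        assert np.all(np.abs(intervals - 600) <= 2 * ep.L_T)  # 60/200 s = 600 samples

    def test_merging_keeps_minimum_separation(self):
        params = HeartCycleParams(heart_rate=260.0)
        rec, _ = synth_recording(params, duration=5.0, snr_db=15.0, rng_seed=13)
        ep = self.params()
        onsets = detect_s1_onsets(rec, ep).s1_onsets
        assert np.all(np.diff(onsets) >= round(ep.s * ep.fs))

    def test_threshold_factor_validation(self):
        with pytest.raises(ValueError):
            EnvelopeParams(a=0.5, b=0.6)


class TestDetectS2:
    def test_s2_found_between_s1_pairs(self):
        params = HeartCycleParams(heart_rate=240.0, jitter_sd=0.0)
        rec, truth = synth_recording(params, duration=5.0, snr_db=20.0, rng_seed=21)
        ep = EnvelopeParams()
        env = extract_envelope(rec.samples, ep)
        s1 = double_threshold_onsets(env, ep).s1_onsets
        s2, skipped = detect_s2_onsets(env, s1, ep)
        assert skipped <= 1
        for onset in s2:
            i = np.searchsorted(s1, onset) - 1
            assert s1[i] < onset < s1[i + 1]
        # each detected S2 within 2 half-windows of a true one
        for onset in s2:
            assert np.min(np.abs(truth.s2_onsets - onset)) <= 2 * ep.L_T


class TestExtractFrames:
    def rec(self, n=4000):
        return Recording(samples=np.random.default_rng(0).standard_normal(n),
                         fs=2000.0, subject_id="r1", group="survival")

    def test_frame_count_and_width(self):
        fs = extract_frames(self.rec(), np.array([0, 1500]), frame_len=1001)
        assert fs.frames.shape == (2, 1001)
        assert list(fs.labels) == ["survival", "survival"]
        assert list(fs.onsets) == [0, 1500]

    def test_overrunning_onset_dropped(self):
        fs = extract_frames(self.rec(), np.array([0, 3500]), frame_len=1001)
        assert len(fs) == 1

    def test_no_valid_onsets_empty(self):
        fs = extract_frames(self.rec(100), np.array([50]), frame_len=1001)
        assert len(fs) == 0

    def test_frames_standardized(self):
        fs = extract_frames(self.rec(), np.array([100, 2000]))
        np.testing.assert_allclose(fs.frames.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(fs.frames.std(axis=1), 1.0, rtol=1e-9)

    def test_synthetic_recording_frame_count(self):
        params = HeartCycleParams(heart_rate=240.0, jitter_sd=0.0)
        rec, _ = synth_recording(params, duration=5.0, snr_db=20.0, rng_seed=17,
                                 subject_id="x", group="sudden_death")
        onsets = detect_s1_onsets(rec)
        frames = extract_frames(rec, onsets)
        # 20 onsets; the last may overrun the 0.5 s frame window
        assert len(frames) in (19, 20)
        assert frames.frame_len == 1001

    def test_hdf5_round_trip(self, tmp_path):
        fs = extract_frames(self.rec(), np.array([0, 1500]))
        fs.save_hdf5(tmp_path / "frames.h5")
        back = FrameSet.load_hdf5(tmp_path / "frames.h5")
        assert back.frames.shape == fs.frames.shape
        np.testing.assert_allclose(back.frames, fs.frames, atol=1e-6)
        assert list(back.subjects) == list(fs.subjects)
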