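"""Signal-to-TFR pipeline: segmentation, filtering, STFT framing, scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from ebdl.tfr_pipeline import (
    GAIT_STFT, VITAL_STFT, DatasetSplit, RadarSegment, STFTConfig,
    bandpass_filter, compose_vital_sample, log_scale, mix_augment,
    normalized_freq_axis, segment_signal, split_dataset, standardize,
    stft_spectrogram,
)

from conftest import make_tfr


def make_signal(n, fs=100.0, label=0):
    t = np.arange(n) / fs
    return RadarSegment(samples=np.exp(2j * np.pi * 3.0 * t), sampling_rate=fs,
                        subject_id="s0", label=label)


class TestSegmentation:
    def test_twenty_second_windows_at_100hz_have_2000_samples(self):
        sig = make_signal(7000)
        segs = segment_signal(sig, window_seconds=20.0, overlap_fraction=0.5)
        assert segs and all(len(s) == 2000 for s in segs)

    def test_start_positions_enumerated(self):
        sig = make_signal(3000)
        segs = segment_signal(sig, window_seconds=20.0, overlap_fraction=0.5)
        assert len(segs) == 2
        assert np.array_equal(segs[0].samples, sig.samples[0:2000])
        assert np.array_equal(segs[1].samples, sig.samples[1000:3000])

    def test_signal_shorter_than_window_gives_empty_list(self):
        assert segment_signal(make_signal(1999), 20.0, 0.5) == []

    @given(n=st.integers(10, 400), win=st.integers(5, 120),
           ov=st.sampled_from([0.0, 0.25, 0.5, 0.75]))
    @settings(max_examples=40, deadline=None)
    def test_segments_are_contiguous_slices_at_fixed_stride(self, n, win, ov):
        sig = make_signal(n, fs=1.0)
        hop = int(round(win * (1 - ov)))
        if hop < 1:
            return
        segs = segment_signal(sig, window_seconds=float(win), overlap_fraction=ov)
        expected_starts = list(range(0, n - win + 1, hop))
        assert len(segs) == len(expected_starts)
        for s, start in zip(segs, expected_starts):
            assert np.array_equal(s.samples, sig.samples[start:start + win])


class TestBandpass:
    """Oracle: the designed filter's analytic magnitude response (sosfreqz)."""

    @pytest.mark.parametrize("tone_hz", [10.0, 40.0])
    def test_tone_power_matches_analytic_response(self, tone_hz):
        fs, n = 100.0, 20000
        t = np.arange(n) / fs
        sig = RadarSegment(np.exp(2j * np.pi * tone_hz * t), fs)
        out = bandpass_filter(sig, 0.1, 20.0, order=4)
        sos = sps.butter(4, [0.1, 20.0], btype="bandpass", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=[tone_hz], fs=fs)
        gain = np.abs(h[0]) ** 2
        # steady-state power after the transient
        tail = out.samples[n // 2:]
        measured = np.mean(np.abs(tail) ** 2)
        assert measured == pytest.approx(gain, rel=0.01)
        if tone_hz == 10.0:
            assert measured == pytest.approx(1.0, rel=0.01)  # in passband
        else:
            assert measured < 10 ** (-3)  # far beyond the 4th-order roll-off

    def test_zero_signal_stays_zero(self):
        sig = RadarSegment(np.zeros(500, complex), 100.0)
        assert np.allclose(bandpass_filter(sig, 0.1, 20.0).samples, 0)

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(make_signal(100), 20.0, 0.1)


class TestSTFT:
    def test_vital_recipe_framing(self):
        spec = stft_spectrogram(make_signal(2000), VITAL_STFT)
        assert spec.shape == (94, 512)  # floor((2000-128)/20)+1 frames

    def test_single_frame_when_signal_equals_window(self):
        cfg = STFTConfig(n_dft=512, window_kind="kaiser", window_length=512,
                         overlap=256)
        spec = stft_spectrogram(make_signal(512), cfg)
        assert spec.shape == (1, 512)

    def test_zero_segment_gives_zero_spectrogram(self):
        sig = RadarSegment(np.zeros(300, complex), 100.0)
        cfg = STFTConfig(n_dft=64, window_kind="hanning", window_length=64, overlap=32)
        assert np.allclose(stft_spectrogram(sig, cfg), 0)

    def test_too_short_segment_reports_required_length(self):
        with pytest.raises(ValueError, match="128"):
            stft_spectrogram(make_signal(100), VITAL_STFT)

    def test_tone_peaks_at_its_shifted_bin(self):
        # a +3 Hz complex tone at fs=100 must land right of center on the
        # shifted axis, at bin n_dft/2 + round(3/df)
        cfg = STFTConfig(n_dft=256, window_kind="hanning", window_length=128,
                         overlap=64)
        spec = stft_spectrogram(make_signal(1000), cfg)
        peak_bin = np.abs(spec[3]).argmax()
        df = 100.0 / 256
        assert peak_bin == 128 + round(3.0 / df)

    @given(n=st.integers(16, 300), win=st.integers(8, 64),
           ov_frac=st.floats(0.0, 0.9))
    @settings(max_examples=40, deadline=None)
    def test_frame_count_matches_start_enumeration(self, n, win, ov_frac):
        ov = int(win * ov_frac)
        if n < win:
            return
        cfg = STFTConfig(n_dft=64 if win <= 64 else win, window_kind="hanning",
                         window_length=win, overlap=ov)
        spec = stft_spectrogram(make_signal(n, fs=1.0), cfg)
        brute = len(range(0, n - win + 1, win - ov))
        assert spec.shape[0] == brute


class TestScaling:
    def test_log_scale_reference_points(self):
        assert log_scale(np.array([0.0]), "gait")[0] == pytest.approx(-100.0)
        assert log_scale(np.array([0.0]), "vital")[0] == pytest.approx(-50.0)
        assert log_scale(np.array([1.0]), "gait")[0] == pytest.approx(
            20 * np.log10(1 + 1e-5))

    def test_log_scale_strictly_monotone(self, rng):
        x = np.sort(rng.uniform(0, 100, size=500))
        y = log_scale(x, "gait")
        assert np.all(np.diff(y) > 0)

    def test_log_scale_rejects_negative(self):
        with pytest.raises(ValueError):
            log_scale(np.array([-0.1]), "gait")

    def test_standardize_constant_and_idempotent(self, rng):
        assert np.allclose(standardize(np.full((4, 5), 3.3)), 0)
        x = rng.normal(2, 7, size=(20, 30))
        z = standardize(x)
        assert abs(z.mean()) < 1e-9 and abs(z.std() - 1) < 1e-9
        assert np.allclose(standardize(z), z)


class TestComposeVital:
    def test_halves_round_trip(self, rng):
        spec = rng.normal(size=(10, 64)) + 1j * rng.normal(size=(10, 64))
        sample = compose_vital_sample(spec, label=2)
        mag = standardize(log_scale(np.abs(spec[:, 32:]), "vital"))
        phase = standardize(np.angle(spec[:, 32:]))
        assert np.allclose(sample.values[:, :32], mag)
        assert np.allclose(sample.values[:, 32:], phase)
        assert sample.channel_semantics == "magnitude_phase_composite"
        assert sample.values.shape == spec.shape

    def test_negative_half_switch(self, rng):
        spec = rng.normal(size=(6, 16)) + 1j * rng.normal(size=(6, 16))
        s = compose_vital_sample(spec, magnitude_half="negative")
        assert np.allclose(s.values[:, :8],
                           standardize(log_scale(np.abs(spec[:, :8]), "vital")))

    def test_zero_spectrogram_gives_constant_halves(self):
        s = compose_vital_sample(np.zeros((5, 8), complex))
        assert np.allclose(s.values, 0)

    def test_odd_bin_count_rejected(self):
        with pytest.raises(ValueError):
            compose_vital_sample(np.zeros((4, 7), complex))


class TestMixAugment:
    def test_label_follows_minority_sample(self, rng):
        r = make_tfr(rng.normal(size=(4, 8)), label=0)
        a = make_tfr(rng.normal(size=(4, 8)), label=3)
        mixed = mix_augment(r, a)
        assert mixed.label == 3
        assert np.allclose(mixed.values, 0.5 * r.values + 0.5 * a.values)

    def test_self_mix_is_identity_and_opposites_cancel(self, rng):
        x = make_tfr(rng.normal(size=(3, 6)), label=1)
        assert np.allclose(mix_augment(x, x).values, x.values)
        neg = make_tfr(-x.values, label=2)
        assert np.allclose(mix_augment(x, neg).values, 0)

    def test_mix_lies_between_inputs_elementwise(self, rng):
        a = make_tfr(rng.normal(size=(5, 5)), label=0)
        b = make_tfr(rng.normal(size=(5, 5)), label=1)
        m = mix_augment(a, b).values
        lo, hi = np.minimum(a.values, b.values), np.maximum(a.values, b.values)
        assert np.all(m >= lo - 1e-12) and np.all(m <= hi + 1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            mix_augment(make_tfr(np.zeros((3, 4))), make_tfr(np.zeros((3, 6)), 1))


class TestSplit:
    def test_eight_to_one_to_one(self):
        samples = [make_tfr(np.zeros((2, 4)), label=i % 2) for i in range(10)]
        split = split_dataset(samples, ratios=(0.8, 0.1, 0.1), seed=3)
        assert (len(split.train), len(split.validation), len(split.test)) == (8, 1, 1)

    def test_same_seed_reproduces_split(self):
        samples = [make_tfr(np.full((2, 2), i), label=0) for i in range(37)]
        a = split_dataset(samples, seed=5)
        b = split_dataset(samples, seed=5)
        for sa, sb in zip(a.test, b.test):
            assert np.array_equal(sa.values, sb.values)

    @given(n=st.integers(1, 200),
           r=st.tuples(st.floats(0.1, 5), st.floats(0.0, 3), st.floats(0.0, 3)))
    @settings(max_examples=40, deadline=None)
    def test_partition_is_disjoint_and_exhaustive(self, n, r):
        samples = [make_tfr(np.full((1, 2), i), label=0) for i in range(n)]
        split = split_dataset(samples, ratios=r, seed=1)
        ids = [id(s) for part in (split.train, split.validation, split.test)
               for s in part]
        assert len(ids) == n and len(set(ids)) == n
        assert set(ids) == {id(s) for s in samples}
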