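import json
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from speechscreen.audio_io import AudioClip
from speechscreen.mfcc import (
    ExtractionParams,
    FeatureDataset,
    FeatureSegment,
    MelScaleParams,
    apply_hann,
    build_mel_filterbank,
    dct_cepstra,
    extract_mfcc,
    frame_signal,
    hann_window,
    hz_to_mel,
    log_mel_energies,
    mel_constant,
    mel_to_hz,
    power_spectrum,
    pre_emphasize,
    read_feature_json,
    segment_mfcc,
    write_feature_json,
)
from speechscreen.synth import CONTROL_PROFILE, generate_utterance

from _oracles import reference_mfcc


class TestMelScale:
    def test_constant_rounds_to_2595(self):
        assert round(mel_constant(700.0)) == 2595

    def test_constant_at_1000(self):
        assert mel_constant(1000.0) == pytest.approx(1000.0 / math.log10(2.0), rel=1e-12)

    def test_constant_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mel_constant(0.0)

    def test_mel_of_zero_is_zero(self):
        assert hz_to_mel(0.0) == 0.0

    def test_1000_hz_maps_to_1000_mels(self):
        assert hz_to_mel(1000.0) == pytest.approx(1000.0, abs=1e-9)

    @pytest.mark.parametrize("f0", [600.0, 700.0, 850.0, 1000.0])
    def test_1000_hz_pins_1000_mels_for_any_corner(self, f0):
        assert hz_to_mel(1000.0, MelScaleParams(f0)) == pytest.approx(1000.0, abs=1e-9)

    def test_mel_at_corner_frequency(self):
        # f = f0 = 700 -> C * log10(2)
        assert hz_to_mel(700.0) == pytest.approx(mel_constant(700.0) * math.log10(2.0))

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            hz_to_mel(-1.0)

    @given(st.floats(min_value=0.0, max_value=2e4), st.floats(min_value=1e-6, max_value=2e4))
    def test_strictly_increasing(self, f, df):
        assert hz_to_mel(f + df) > hz_to_mel(f)

    @given(st.floats(min_value=0.0, max_value=2e4))
    def test_inverse_round_trip(self, f):
        assert mel_to_hz(hz_to_mel(f)) == pytest.approx(f, abs=1e-6, rel=1e-9)


class TestPreEmphasis:
    def test_alpha_zero_is_identity(self, sine_clip):
        out = pre_emphasize(sine_clip, 0.0)
        np.testing.assert_array_equal(out.samples, sine_clip.samples)

    def test_constant_signal(self):
        clip = AudioClip(np.full(100, 0.5), 8000)
        out = pre_emphasize(clip, 0.97).samples
        assert out[0] == 0.5
        np.testing.assert_allclose(out[1:], 0.03 * 0.5, atol=1e-15)

    def test_alternating_signal(self):
        x = np.empty(64)
        x[::2], x[1::2] = 1.0, -1.0
        out = pre_emphasize(AudioClip(x, 8000), 0.97).samples
        np.testing.assert_allclose(np.abs(out[1:]), 1.97, atol=1e-15)

    @pytest.mark.parametrize("alpha", [-0.1, 1.0, 1.5])
    def test_alpha_out_of_range(self, alpha, sine_clip):
        with pytest.raises(ValueError):
            pre_emphasize(sine_clip, alpha)


class TestFraming:
    def test_exact_fit_single_frame(self):
        clip = AudioClip(np.ones(2048), 44100)
        assert frame_signal(clip, 2048, 512).n_frames == 1

    def test_4096_gives_5_frames(self):
        clip = AudioClip(np.ones(4096), 44100)
        assert frame_signal(clip, 2048, 512).n_frames == 5  # 1 + ceil(2048/512)

    def test_short_signal_zero_padded(self):
        clip = AudioClip(np.ones(1000), 44100)
        stack = frame_signal(clip, 2048, 512)
        assert stack.n_frames == 1
        np.testing.assert_array_equal(stack.frames[0, 1000:], 0.0)
        np.testing.assert_array_equal(stack.frames[0, :1000], 1.0)

    def test_frames_overlap_correctly(self, rng):
        x = rng.normal(size=700)
        stack = frame_signal(AudioClip(x, 8000), 256, 128)
        np.testing.assert_array_equal(stack.frames[1, :128], x[128:256])

    def test_bad_hop_rejected(self):
        with pytest.raises(ValueError):
            frame_signal(AudioClip(np.ones(10), 8000), 4, 8)


class TestHann:
    def test_window_sum_is_half_length(self):
        stack = frame_signal(AudioClip(np.ones(2048), 44100), 2048, 512)
        windowed = apply_hann(stack)
        assert windowed.frames[0].sum() == pytest.approx(1024.0)  # N/2, periodic form

    def test_first_element_zero(self, rng):
        stack = frame_signal(AudioClip(rng.normal(size=4096), 44100), 2048, 512)
        np.testing.assert_array_equal(apply_hann(stack).frames[:, 0], 0.0)

    def test_zero_frames_stay_zero(self):
        stack = frame_signal(AudioClip(np.zeros(4096), 44100), 2048, 512)
        assert not np.any(apply_hann(stack).frames)

    def test_periodic_not_symmetric(self):
        w = hann_window(8)
        assert w[0] == 0.0 and w[4] == pytest.approx(1.0)  # peak at N/2


class TestPowerSpectrum:
    def test_zero_frame_zero_spectrum(self):
        stack = frame_signal(AudioClip(np.zeros(256), 8000), 256, 128)
        assert not np.any(power_spectrum(stack))

    def test_on_grid_cosine_concentrates(self):
        n = 256
        k = 10
        x = np.cos(2 * np.pi * k * np.arange(n) / n)
        stack = frame_signal(AudioClip(x, 8000), n, n)
        spec = power_spectrum(stack)[0]
        others = np.delete(spec, k)
        assert np.all(others <= 1e-9 * spec[k])

    def test_parseval(self, rng):
        n = 512
        x = rng.normal(size=n)
        stack = frame_signal(AudioClip(x, 8000), n, n)
        spec = power_spectrum(stack, n)[0]
        two_sided = spec[0] + spec[-1] + 2.0 * spec[1:-1].sum()  # n even
        assert np.sum(x**2) == pytest.approx(two_sided / n, rel=1e-12)

    def test_nfft_shorter_than_frame_rejected(self):
        stack = frame_signal(AudioClip(np.ones(256), 8000), 256, 128)
        with pytest.raises(ValueError):
            power_spectrum(stack, 128)


class TestFilterBank:
    def test_single_triangle_spans_band(self):
        bank = build_mel_filterbank(1, 256, 8000)
        assert bank.weights.shape == (1, 129)
        assert bank.weights.max() > 0

    def test_centres_equally_spaced_in_mels(self):
        bank = build_mel_filterbank(40, 2048, 44100)
        centre_mels = hz_to_mel(bank.band_edges_hz[:, 1])
        diffs = np.diff(centre_mels)
        assert np.max(np.abs(diffs - diffs[0])) <= 1e-9 * diffs[0]

    def test_full_coverage_between_first_and_last_centre(self):
        bank = build_mel_filterbank(40, 2048, 44100)
        freqs = np.arange(1025) * 44100 / 2048
        inside = (freqs > bank.band_edges_hz[0, 1]) & (freqs < bank.band_edges_hz[-1, 1])
        assert np.all(bank.weights.sum(axis=0)[inside] > 0)

    def test_unimodal_nonnegative(self):
        bank = build_mel_filterbank(20, 1024, 16000)
        assert np.all(bank.weights >= 0)
        for row in bank.weights:
            peak = row.argmax()
            assert np.all(np.diff(row[:peak + 1]) >= -1e-15)
            assert np.all(np.diff(row[peak:]) <= 1e-15)

    def test_too_many_filters_rejected(self):
        with pytest.raises(ValueError, match="resolution|empty"):
            build_mel_filterbank(512, 256, 8000)

    def test_bad_band_rejected(self):
        with pytest.raises(ValueError):
            build_mel_filterbank(10, 1024, 16000, fmin=4000, fmax=1000)


class TestLogMelEnergies:
    def test_zero_spectrum_hits_floor(self):
        bank = build_mel_filterbank(10, 256, 8000)
        out = log_mel_energies(np.zeros((3, 129)), bank, rel_floor=1e-10)
        np.testing.assert_allclose(out, -10.0)

    def test_scaling_by_ten_shifts_by_one(self, rng):
        bank = build_mel_filterbank(10, 256, 8000)
        spec = rng.uniform(0, 1, size=(4, 129))
        np.testing.assert_allclose(
            log_mel_energies(spec * 10.0, bank), log_mel_energies(spec, bank) + 1.0,
            atol=1e-12,
        )

    def test_monotone_in_spectrum(self, rng):
        bank = build_mel_filterbank(10, 256, 8000)
        spec = rng.uniform(0, 1, size=(4, 129))
        bigger = spec + rng.uniform(0, 1, size=spec.shape)
        assert np.all(log_mel_energies(bigger, bank) >= log_mel_energies(spec, bank) - 1e-12)

    def test_shape_mismatch_rejected(self):
        bank = build_mel_filterbank(10, 256, 8000)
        with pytest.raises(ValueError):
            log_mel_energies(np.zeros((3, 100)), bank)


class TestDct:
    def test_constant_vector_only_dc(self):
        out = dct_cepstra(np.full((2, 16), 3.0), 16).coefficients
        assert out[0, 0] == pytest.approx(3.0 * 4.0)  # sqrt(16) * mean
        np.testing.assert_allclose(out[:, 1:], 0.0, atol=1e-12)

    def test_orthonormal_inverse(self, rng):
        import scipy.fft

        x = rng.normal(size=(5, 32))
        full = dct_cepstra(x, 32).coefficients
        back = scipy.fft.idct(full, type=2, norm="ortho", axis=1)
        np.testing.assert_allclose(back, x, atol=1e-9)

    def test_13_of_128(self, rng):
        out = dct_cepstra(rng.normal(size=(4, 128)), 13)
        assert out.coefficients.shape == (4, 13)

    def test_too_many_coefficients_rejected(self, rng):
        with pytest.raises(ValueError):
            dct_cepstra(rng.normal(size=(4, 10)), 11)


class TestExtract:
    def test_two_second_clip_framing_arithmetic(self, rng):
        clip = AudioClip(0.5 * rng.uniform(-1, 1, 88200), 44100)
        mat = extract_mfcc(clip)
        assert mat.coefficients.shape == (170, 13)  # 1 + ceil((88200-2048)/512)

    def test_silence_rows_identical(self):
        clip = AudioClip(np.zeros(8192), 44100)
        mat = extract_mfcc(clip).coefficients
        np.testing.assert_allclose(mat, np.broadcast_to(mat[0], mat.shape), atol=1e-12)

    def test_matches_reference_implementation(self):
        clip = generate_utterance(CONTROL_PROFILE, 1.2, 22050, seed=5)
        ours = extract_mfcc(clip, ExtractionParams()).coefficients
        ref = reference_mfcc(clip.samples, 22050)
        assert np.max(np.abs(ours - ref)) < 1e-5

    def test_equals_stage_composition(self, rng):
        p = ExtractionParams(n_mels=40)
        clip = AudioClip(0.5 * rng.uniform(-1, 1, 20000), 16000)
        staged = dct_cepstra(
            log_mel_energies(
                power_spectrum(apply_hann(frame_signal(
                    pre_emphasize(clip, p.pre_emphasis), p.n_fft, p.hop_length)), p.n_fft),
                build_mel_filterbank(p.n_mels, p.n_fft, 16000,
                                     MelScaleParams(p.corner_frequency_hz)),
                p.rel_floor,
            ),
            p.n_mfcc,
        ).coefficients
        np.testing.assert_array_equal(extract_mfcc(clip, p).coefficients, staged)

    def test_time_shift_covariance(self):
        clip = generate_utterance(CONTROL_PROFILE, 1.0, 16000, seed=9)
        p = ExtractionParams(n_mels=40)
        base = extract_mfcc(clip, p).coefficients
        delayed_samples = np.concatenate([np.zeros(p.hop_length), clip.samples])
        delayed = extract_mfcc(
            AudioClip(delayed_samples, 16000), p
        ).coefficients
        # interior rows shift by exactly one hop (last rows touch tail padding)
        np.testing.assert_allclose(delayed[1:-1], base[:-1], atol=1e-6)


class TestSegmentation:
    def _mat(self, n_frames, rng):
        from speechscreen.mfcc import MFCCMatrix

        return MFCCMatrix(rng.normal(size=(n_frames, 13)), 13, "p1")

    def test_170_frames_gives_3_segments(self, rng):
        segs = segment_mfcc(self._mat(170, rng), 50, label=1)
        assert len(segs) == 3  # floor(170/50); 20 frames dropped
        assert all(s.features.shape == (50, 13) for s in segs)

    def test_short_matrix_warns_empty(self, rng):
        with pytest.warns(UserWarning, match="no segments"):
            segs = segment_mfcc(self._mat(49, rng), 50, label=0)
        assert segs == []

    def test_labels_inherited(self, rng):
        segs = segment_mfcc(self._mat(170, rng), 50, label=1, participant_id="x")
        assert all(s.label == 1 and s.participant_id == "x" for s in segs)


class TestFeatureJson:
    def _dataset(self, rng, n=4):
        segs = [
            FeatureSegment(rng.normal(size=(10, 13)), i % 2, f"p{i}")
            for i in range(n)
        ]
        return FeatureDataset(segments=segs,
                              extraction_params=ExtractionParams(frames_per_segment=10))

    def test_round_trip(self, tmp_path, rng):
        ds = self._dataset(rng)
        path = write_feature_json(ds, tmp_path / "f.json")
        back = read_feature_json(path)
        assert back.label_names == ds.label_names
        assert back.extraction_params == ds.extraction_params
        for a, b in zip(back.segments, ds.segments):
            np.testing.assert_array_equal(a.features, b.features)
            assert (a.label, a.participant_id) == (b.label, b.participant_id)

    def test_mixed_shapes_refused(self, tmp_path, rng):
        ds = self._dataset(rng)
        ds.segments.append(FeatureSegment(rng.normal(size=(7, 13)), 0, "odd"))
        with pytest.raises(ValueError, match="mixed|shape"):
            write_feature_json(ds, tmp_path / "f.json")

    def test_unknown_label_refused(self, tmp_path, rng):
        ds = self._dataset(rng)
        path = write_feature_json(ds, tmp_path / "f.json")
        payload = json.loads(path.read_text())
        payload["labels"][0] = 5
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="label"):
            read_feature_json(path)

    def test_empty_dataset_refused(self, tmp_path):
        ds = FeatureDataset(segments=[])
        with pytest.raises(ValueError):
            write_feature_json(ds, tmp_path / "f.json")
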