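"""Acoustic feature extraction: framing, pitch, perturbation, spectra."""

import numpy as np
import pytest
from scipy.fft import dct

from attnspeech.audio import Waveform
from attnspeech.features import (
    FeatureConfig,
    FeatureSchema,
    FrameParams,
    _frames_raw,
    delta_regression,
    extract_all,
    extract_f0,
    extract_jitter,
    extract_shimmer,
    extract_spectral,
    extract_voicing_harmonicity,
    frame_signal,
    mark_pitch_periods,
    mel_filterbank,
)
from attnspeech.synthetic import gen_waveform


class TestFraming:
    def test_frame_count_one_second(self, frame_params):
        w = Waveform(np.zeros(16_000), 16_000)
        frames = frame_signal(w, frame_params)
        assert frames.shape == (98, 400)  # 1 + floor((16000-400)/160)

    def test_single_frame_equals_tapered_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        w = Waveform(x, 16_000)
        frames = frame_signal(w, FrameParams())
        assert frames.shape == (1, 400)
        np.testing.assert_allclose(frames[0], x * np.hamming(400))

    def test_non_overlapping_tiling_when_hop_equals_frame(self):
        x = np.arange(800, dtype=float) / 800
        w = Waveform(x, 16_000)
        p = FrameParams(frame_len=0.025, hop=0.025, window="rect")
        frames = frame_signal(w, p)
        assert frames.shape == (2, 400)
        np.testing.assert_allclose(frames.ravel(), x)

    def test_too_short_signal_raises_with_minimum_duration(self):
        w = Waveform(np.zeros(100), 16_000)
        with pytest.raises(ValueError, match="25 ms"):
            frame_signal(w, FrameParams())


class TestF0:
    def test_sine_recovered_within_2hz(self, sine_220, frame_params):
        frames = _frames_raw(sine_220, frame_params)
        f0 = extract_f0(frames, sine_220.rate)
        interior = f0[5:-5]
        assert np.all(np.abs(interior - 220.0) < 2.0)

    def test_white_noise_mostly_unvoiced(self, white_noise, frame_params):
        frames = _frames_raw(white_noise, frame_params)
        f0 = extract_f0(frames, white_noise.rate)
        assert np.mean(f0 == 0) > 0.5

    def test_silence_all_unvoiced(self, frame_params):
        w = Waveform(np.zeros(8000), 16_000)
        f0 = extract_f0(_frames_raw(w, frame_params), 16_000)
        assert np.all(f0 == 0)

    def test_invalid_range_rejected(self, sine_220, frame_params):
        frames = _frames_raw(sine_220, frame_params)
        with pytest.raises(ValueError):
            extract_f0(frames, sine_220.rate, fmin=500, fmax=100)


def _perturbation_tracks(jitter_frac, shimmer_frac, seed=3):
    p = FrameParams()
    w, _ = gen_waveform(
        f0=220, jitter_frac=jitter_frac, shimmer_frac=shimmer_frac,
        duration=1.5, seed=seed,
    )
    frames = _frames_raw(w, p)
    f0 = extract_f0(frames, w.rate)
    marks = mark_pitch_periods(w, f0, p)
    times = p.frame_times(frames.shape[0], w.rate)
    voiced = f0 > 0
    return extract_jitter(marks, times)[voiced], extract_shimmer(marks, times)[voiced]


class TestJitterShimmer:
    def test_periodic_tone_has_negligible_jitter(self):
        jitter, shimmer = _perturbation_tracks(0.0, 0.0)
        assert np.median(jitter) < 0.005
        assert np.median(shimmer) < 0.01

    def test_injected_jitter_recovered_within_30pct(self):
        jitter, _ = _perturbation_tracks(0.02, 0.0)
        assert abs(np.median(jitter) - 0.02) < 0.3 * 0.02

    def test_injected_shimmer_recovered_within_30pct(self):
        _, shimmer = _perturbation_tracks(0.0, 0.05)
        assert abs(np.median(shimmer) - 0.05) < 0.3 * 0.05

    def test_unvoiced_input_gives_zeros(self, white_noise, frame_params):
        frames = _frames_raw(white_noise, frame_params)
        f0 = extract_f0(frames, white_noise.rate)
        marks = mark_pitch_periods(white_noise, f0, frame_params)
        times = frame_params.frame_times(frames.shape[0], white_noise.rate)
        assert np.all(extract_jitter(marks, times) == 0)
        assert np.all(extract_shimmer(marks, times) == 0)


class TestSpectral:
    def test_lsp_strictly_ascending(self, rng):
        frames = rng.normal(size=(20, 400))
        out = extract_spectral(frames, 16_000)
        diffs = np.diff(out["lsp"], axis=1)
        assert np.all(diffs > 0)

    def test_delta_of_constant_track_is_zero(self):
        const = np.ones((50, 13)) * 3.7
        np.testing.assert_allclose(delta_regression(const), 0.0, atol=1e-12)

    def test_delta_of_linear_ramp_is_slope(self):
        ramp = np.arange(30, dtype=float)[:, None]
        d = delta_regression(ramp)
        # away from the replicated edges the regression slope is exact
        np.testing.assert_allclose(d[2:-2, 0], 1.0, atol=1e-12)

    def test_mfcc_matches_direct_dct_of_log_mel(self, rng):
        """One-frame oracle: MFCC = DCT-II(log Mel energies) computed directly."""
        frame = rng.normal(size=(1, 400)) * np.hamming(400)
        out = extract_spectral(frame, 16_000)
        n_fft = 512
        power = np.abs(np.fft.rfft(frame[0], n_fft)) ** 2
        fb = mel_filterbank(16_000, n_fft, 26)
        log_mel = np.log(fb @ power + 1e-10)
        expected = dct(log_mel, type=2, norm="ortho")[:13]
        np.testing.assert_allclose(out["mfcc"][0], expected, rtol=1e-8)

    def test_degenerate_frame_gives_zero_lpc(self):
        frames = np.zeros((3, 400))
        out = extract_spectral(frames, 16_000)
        np.testing.assert_array_equal(out["lpc"], 0.0)
        assert np.all(np.diff(out["lsp"], axis=1) > 0)  # fallback grid ascending


class TestVoicingHarmonicity:
    def test_pure_sine_near_upper_clip(self, sine_220, frame_params):
        frames = _frames_raw(sine_220, frame_params)
        f0 = extract_f0(frames, sine_220.rate)
        vh = extract_voicing_harmonicity(frames, sine_220.rate, f0)
        interior = slice(5, -5)
        assert np.median(vh["HNR"][interior]) > 25.0
        rms = 0.5 / np.sqrt(2)
        assert np.median(vh["noiseERMS"][interior]) < 0.05 * rms

    def test_white_noise_low_voicing_low_hnr(self, white_noise, frame_params):
        frames = _frames_raw(white_noise, frame_params)
        f0 = extract_f0(frames, white_noise.rate)
        vh = extract_voicing_harmonicity(frames, white_noise.rate, f0)
        assert np.median(vh["voiceProb"]) < 0.45
        assert np.median(vh["HNR"]) < -20.0

    def test_snr10_recovered_within_3db(self):
        w, _ = gen_waveform(f0=220, snr_db=10.0, duration=1.5, seed=3)
        p = FrameParams()
        frames = _frames_raw(w, p)
        f0 = extract_f0(frames, w.rate)
        vh = extract_voicing_harmonicity(frames, w.rate, f0)
        voiced = f0 > 0
        assert voiced.mean() > 0.5
        assert abs(np.median(vh["HNR"][voiced]) - 10.0) < 3.0

    def test_silence_zero_energy_lower_clip(self, frame_params):
        w = Waveform(np.zeros(8000), 16_000)
        frames = _frames_raw(w, frame_params)
        vh = extract_voicing_harmonicity(frames, 16_000, np.zeros(frames.shape[0]))
        assert np.all(vh["voiceProb"] == 0)
        assert np.all(vh["harmonicERMS"] == 0)
        assert np.all(vh["HNR"] == -40.0)


class TestExtractAll:
    def test_three_seconds_gives_298_frames_and_padded_schema(self):
        t = np.arange(48_000) / 16_000
        w = Waveform(0.3 * np.sin(2 * np.pi * 150 * t), 16_000)
        fm = extract_all(w)
        assert fm.n_frames == 298
        assert fm.schema.z == 80  # 77 descriptors + 3 pad columns
        assert fm.schema.z % 8 == 0
        assert np.all(np.isfinite(fm.values))
        pad_cols = [i for i, n in enumerate(fm.schema.names) if n.startswith("pad_")]
        assert np.all(fm.values[:, pad_cols] == 0)

    def test_deterministic(self, sine_220):
        a = extract_all(sine_220)
        b = extract_all(sine_220)
        np.testing.assert_array_equal(a.values, b.values)

    def test_schema_subset(self, sine_220):
        cfg = FeatureConfig(groups=("mfcc",), pad_to_multiple=1)
        fm = extract_all(sine_220, cfg=cfg)
        assert fm.schema.z == 13
        assert fm.schema.names == tuple(f"mfcc_{i}" for i in range(13))

    def test_silence_produces_finite_features(self):
        w = Waveform(np.zeros(16_000), 16_000)
        fm = extract_all(w)
        assert np.all(np.isfinite(fm.values))

    def test_error_carries_segment_id(self):
        w = Waveform(np.zeros(100), 16_000)
        with pytest.raises(ValueError, match="seg-7"):
            extract_all(w, source_id="seg-7")


def test_schema_padding_divisible_by_head_counts():
    schema = FeatureSchema.from_config(FeatureConfig())
    for heads in (1, 2, 4, 8):
        assert schema.z % heads == 0
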