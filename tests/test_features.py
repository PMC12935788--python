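"""Acoustic feature extractors on synthetic signals with known structure."""

import numpy as np
import pytest

from vococoord.errors import InvalidInputError
from vococoord.features import (
    cpp_from_cepstrum,
    estimate_cpp,
    estimate_envelope,
    estimate_f0,
    estimate_formants,
    estimate_hnr,
    estimate_mfcc,
    extract_all,
)
from vococoord.synthetic import make_vocalization
from vococoord.types import Waveform


def _sinusoid(freq=220.0, amp=0.8, dur=1.0, fs=16000.0):
    t = np.arange(int(dur * fs)) / fs
    return Waveform(amp * np.sin(2 * np.pi * freq * t), fs)


class TestF0:
    def test_pure_tone_median(self):
        f0 = estimate_f0(_sinusoid(220.0))
        assert 215.0 <= np.nanmedian(f0.valid_values()) <= 225.0

    def test_output_rate_and_length(self):
        f0 = estimate_f0(_sinusoid(dur=1.0))
        assert f0.rate_hz == 1000.0
        assert abs(f0.n_frames - 1000) <= 1

    @pytest.mark.parametrize("seed", range(10))
    def test_noise_is_mostly_unvoiced(self, seed):
        rng = np.random.default_rng(seed)
        w = Waveform(0.5 * rng.standard_normal(16000), 16000.0)
        assert estimate_f0(w).valid_fraction() < 0.2

    def test_vocalization_tracks_constant_pitch(self):
        w = make_vocalization(1.0, f0_contour=220.0, rate_hz=44100.0, seed=0)
        f0 = estimate_f0(w)
        assert abs(np.nanmedian(f0.valid_values()) - 220.0) < 5.0

    def test_empty_audio_rejected(self):
        with pytest.raises(InvalidInputError):
            estimate_f0(Waveform(np.array([]), 16000.0))

    def test_f0_positive_on_valid_frames(self, vowel):
        f0 = estimate_f0(vowel)
        assert (f0.valid_values() > 0).all()


class TestHNR:
    def test_pure_tone_is_strongly_harmonic(self):
        hnr = estimate_hnr(_sinusoid())
        assert np.nanmean(hnr.valid_values()) > 20.0

    def test_noise_scores_low_even_at_best_lag(self, noise_wave):
        hnr = estimate_hnr(noise_wave, mask_unvoiced=False)
        assert np.nanmean(hnr.values) < 5.0

    def test_output_rate(self, vowel):
        assert estimate_hnr(vowel).rate_hz == 100.0


class TestCPP:
    def test_regression_line_cepstrum_scores_zero(self):
        q = np.linspace(0.001, 0.016, 200)
        cep = 3.0 * q + 0.5  # exactly its own regression line
        assert cpp_from_cepstrum(cep, q, (0.001, 0.016)) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_vowel_beats_noise_at_equal_rms(self, seed):
        w = make_vocalization(1.0, f0_contour=220.0, rate_hz=16000.0, seed=seed)
        rng = np.random.default_rng(seed)
        n = rng.standard_normal(w.samples.size)
        n *= np.sqrt(np.mean(w.samples**2) / np.mean(n**2))
        cpp_v = estimate_cpp(w)
        cpp_n = estimate_cpp(Waveform(n, 16000.0), mask_unvoiced=False)
        assert np.nanmean(cpp_v.valid_values()) > np.nanmean(cpp_n.values)

    def test_deterministic(self, vowel):
        a = estimate_cpp(vowel)
        b = estimate_cpp(vowel)
        assert np.array_equal(a.values, b.values, equal_nan=True)
        assert np.array_equal(a.mask, b.mask)

    def test_output_rate(self, vowel):
        assert estimate_cpp(vowel).rate_hz == 100.0


class TestFormants:
    def test_recovers_synthesized_resonances(self):
        w = make_vocalization(
            1.0, f0_contour=120.0, formant_freqs=(500.0, 1500.0, 2500.0),
            rate_hz=16000.0, seed=1,
        )
        fm = estimate_formants(w)
        for name, nominal in zip(("F1", "F2", "F3"), (500.0, 1500.0, 2500.0)):
            med = np.nanmedian(fm[name].valid_values())
            assert abs(med - nominal) / nominal < 0.10

    def test_silence_is_masked(self):
        w = Waveform(np.zeros(8000), 16000.0)
        fm = estimate_formants(w)
        assert not fm["F1"].mask.any()

    def test_output_rate(self, vowel):
        fm = estimate_formants(vowel)
        assert all(fm[k].rate_hz == 100.0 for k in ("F1", "F2", "F3"))


class TestMFCC:
    def test_gain_invariance(self, vowel):
        m1 = estimate_mfcc(vowel)
        m2 = estimate_mfcc(Waveform(vowel.samples * 10.0, vowel.rate_hz))
        for k in m1:
            assert np.abs(m1[k].values - m2[k].values).max() < 1e-6

    def test_output_rate_and_count(self, vowel):
        m = estimate_mfcc(vowel, n_coeffs=5)
        assert set(m) == {f"MFCC{i}" for i in range(1, 6)}
        assert all(tr.rate_hz == 200.0 for tr in m.values())

    def test_deterministic(self, vowel):
        a = estimate_mfcc(vowel)["MFCC1"].values
        b = estimate_mfcc(vowel)["MFCC1"].values
        assert np.array_equal(a, b)


class TestEnvelope:
    def test_constant_amplitude_recovered(self):
        env = estimate_envelope(_sinusoid(freq=440.0, amp=0.5))
        mid = env.values[20:-20]
        assert np.abs(mid - 0.5).max() / 0.5 < 0.05

    def test_am_modulation_peak(self):
        fs = 16000.0
        t = np.arange(int(4 * fs)) / fs
        x = (1 + 0.5 * np.sin(2 * np.pi * 4.0 * t)) * np.sin(2 * np.pi * 500.0 * t)
        env = estimate_envelope(Waveform(0.5 * x / np.abs(x).max(), fs))
        e = env.values - env.values.mean()
        freqs = np.fft.rfftfreq(e.size, d=1 / 100.0)
        spec = np.abs(np.fft.rfft(e))
        assert abs(freqs[np.argmax(spec)] - 4.0) < 0.5

    def test_output_rate_and_full_validity(self, vowel):
        env = estimate_envelope(vowel)
        assert env.rate_hz == 100.0
        assert env.mask.all()

    def test_scales_linearly_with_amplitude(self, vowel):
        e1 = estimate_envelope(vowel).values
        e2 = estimate_envelope(Waveform(vowel.samples * 3.0, vowel.rate_hz)).values
        assert np.abs(e2 - 3.0 * e1).max() < 1e-8


class TestExtractAll:
    def test_full_channel_registry(self, vowel):
        rec = extract_all(vowel)
        expected = {"F0", "HNR", "CPP", "ENV", "F1", "F2", "F3",
                    "MFCC1", "MFCC2", "MFCC3", "MFCC4", "MFCC5"}
        assert expected.issubset(rec.channels)

    def test_registry_rates(self, vowel):
        rec = extract_all(vowel)
        assert rec["F0"].rate_hz == 1000.0
        assert all(rec[f"MFCC{i}"].rate_hz == 200.0 for i in range(1, 6))
        for name in ("HNR", "CPP", "ENV", "F1", "F2", "F3"):
            assert rec[name].rate_hz == 100.0

    def test_frame_counts_scale_with_duration(self):
        w = make_vocalization(3.0, f0_contour=220.0, rate_hz=16000.0, seed=0)
        rec = extract_all(w)
        assert abs(rec["F0"].n_frames - 3000) <= 1
        assert abs(rec["ENV"].n_frames - 300) <= 1

    def test_silence_masks_laryngeal_channels(self):
        rec = extract_all(Waveform(np.zeros(16000), 16000.0))
        for name in ("F0", "HNR", "CPP"):
            assert not rec[name].mask.any()

    def test_laryngeal_channels_share_one_mask(self, vowel):
        rec = extract_all(vowel)
        f0_at_100 = rec["F0"].mask[::10][: rec["HNR"].n_frames]
        assert np.array_equal(rec["HNR"].mask, f0_at_100)
        assert np.array_equal(rec["CPP"].mask[: f0_at_100.size], f0_at_100)

    def test_amplitude_invariance_of_spectral_channels(self, vowel):
        r1 = extract_all(vowel)
        r2 = extract_all(Waveform(vowel.samples * 5.0, vowel.rate_hz))
        for name in ("F0", "F1", "F2", "F3", "HNR", "CPP"):
            a, b = r1[name].values, r2[name].values
            both = r1[name].mask & r2[name].mask
            denom = np.maximum(np.abs(a[both]), 1e-9)
            assert (np.abs(a[both] - b[both]) / denom).max() < 1e-4

    def test_time_shift_moves_trajectories_by_whole_frames(self):
        w = make_vocalization(2.0, f0_contour=200.0, rate_hz=16000.0, seed=3)
        shift_frames = 3  # 30 ms = 3 frames at 100 Hz
        shift_samples = int(0.03 * w.rate_hz)
        shifted = Waveform(
            np.concatenate([np.zeros(shift_samples), w.samples]), w.rate_hz
        )
        e1 = estimate_envelope(w).values
        e2 = estimate_envelope(shifted).values
        # compare away from edges
        a = e1[20:120]
        b = e2[20 + shift_frames : 120 + shift_frames]
        assert np.abs(a - b).max() < 0.02 * np.abs(a).max()
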