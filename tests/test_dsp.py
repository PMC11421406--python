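"""Masker-construction DSP: pauses, spectral shaping, superposition."""

import numpy as np
import pytest

from speechresp.dsp import (AudioSegment, PauseInterval, band_levels,
                            detect_pauses, envelope_modulation_depth_db,
                            read_wav, rearrange_sections, rms_normalize,
                            shape_spectrum, shorten_pauses,
                            synthesize_stationary, third_octave_bands,
                            write_wav)

SR = 16000


def _noise(duration_s, seed=0, sr=SR):
    rng = np.random.default_rng(seed)
    return rng.normal(0, 0.1, int(duration_s * sr))


def _burst_pause_burst(pause_s=0.6, sr=SR):
    """1 s noise - pause - 1 s noise fixture."""
    x = np.concatenate([_noise(1.0, 1, sr), np.zeros(int(pause_s * sr)),
                        _noise(1.0, 2, sr)])
    return AudioSegment(samples=x, rate=sr)


class TestDetectPauses:
    def test_single_gap_found_with_correct_length(self):
        audio = _burst_pause_burst(0.6)
        pauses = detect_pauses(audio)
        assert len(pauses) == 1
        assert pauses[0].duration_s == pytest.approx(0.6, abs=0.03)

    def test_continuous_noise_has_no_pauses(self):
        audio = AudioSegment(samples=_noise(2.0, 3), rate=SR)
        assert detect_pauses(audio) == []

    def test_min_length_filter(self):
        x = np.concatenate([_noise(0.5, 1), np.zeros(int(0.3 * SR)),
                            _noise(0.5, 2), np.zeros(int(0.3 * SR)),
                            _noise(0.5, 3)])
        audio = AudioSegment(samples=x, rate=SR)
        assert detect_pauses(audio, min_pause_ms=400) == []
        assert len(detect_pauses(audio, min_pause_ms=250)) == 2

    def test_silent_input_is_one_pause(self):
        audio = AudioSegment(samples=np.zeros(SR), rate=SR)
        pauses = detect_pauses(audio)
        assert len(pauses) == 1
        assert pauses[0].duration_s == pytest.approx(1.0)


class TestShortenPauses:
    def test_long_pause_cut_to_cap(self):
        audio = _burst_pause_burst(0.6)
        pauses = detect_pauses(audio)
        out = shorten_pauses(audio, pauses, max_pause_ms=250)
        removed = audio.duration_s - out.duration_s
        # exactly the detected excess is excised
        expected = sum(p.duration_s - 0.25 for p in pauses)
        assert removed == pytest.approx(expected, abs=1e-9)
        assert removed == pytest.approx(0.35, abs=0.015)  # one detection frame
        again = detect_pauses(out, min_pause_ms=250 + 10)  # +1 frame tolerance
        assert again == []

    def test_short_pauses_untouched(self):
        audio = _burst_pause_burst(0.2)
        pauses = detect_pauses(audio, min_pause_ms=100)
        out = shorten_pauses(audio, pauses, max_pause_ms=250)
        assert np.array_equal(out.samples, audio.samples)

    def test_length_shrinks_by_total_excess(self):
        x = np.concatenate([_noise(0.5, 1), np.zeros(int(0.7 * SR)),
                            _noise(0.5, 2), np.zeros(int(0.4 * SR)),
                            _noise(0.5, 3)])
        audio = AudioSegment(samples=x, rate=SR)
        pauses = detect_pauses(audio)
        out = shorten_pauses(audio, pauses, max_pause_ms=250)
        expected = sum(max(0.0, p.duration_s - 0.25) for p in pauses)
        assert audio.duration_s - out.duration_s == pytest.approx(expected, abs=0.005)

    def test_samples_outside_cuts_preserved(self):
        audio = _burst_pause_burst(0.6)
        out = shorten_pauses(audio, detect_pauses(audio), max_pause_ms=250)
        # leading noise burst ends at 1.0 s; crossfade cannot start before
        # the pause does, so the first ~0.9 s must be bit-identical
        n = int(0.9 * SR)
        assert np.array_equal(out.samples[:n], audio.samples[:n])

    def test_overlapping_pauses_rejected(self):
        audio = _burst_pause_burst(0.6)
        with pytest.raises(ValueError):
            shorten_pauses(audio, [PauseInterval(0.9, 1.4), PauseInterval(1.2, 1.6)])


class TestShapeSpectrum:
    def test_own_spectrum_is_identity_within_tolerance(self):
        audio = AudioSegment(samples=_noise(10.0, 4), rate=SR)
        centers, levels = band_levels(audio)
        out = shape_spectrum(audio, centers, levels)
        _, out_levels = band_levels(out, centers)
        assert np.allclose(out_levels, levels, atol=0.5)

    def test_white_noise_to_pink_slope(self):
        """Shaping white noise to a -6 dB/octave target yields that slope."""
        audio = AudioSegment(samples=_noise(20.0, 5), rate=SR)
        centers = third_octave_bands(SR, f_lo=125, f_hi=4000)
        target = -6.0 * np.log2(centers / 1000.0)
        out = shape_spectrum(audio, centers, target)
        _, measured = band_levels(out, centers)
        slope = np.polyfit(np.log2(centers), measured, 1)[0]
        assert slope == pytest.approx(-6.0, abs=0.5)
        # per-band match up to a common offset
        resid = (measured - target) - (measured - target).mean()
        assert np.max(np.abs(resid)) < 1.0

    def test_level_preserving(self):
        audio = AudioSegment(samples=_noise(5.0, 6), rate=SR)
        centers = third_octave_bands(SR, f_lo=125, f_hi=4000)
        out = shape_spectrum(audio, centers, -3.0 * np.log2(centers / 1000.0))
        assert out.rms == pytest.approx(audio.rms)

    def test_idempotence(self):
        audio = AudioSegment(samples=_noise(10.0, 7), rate=SR)
        centers = third_octave_bands(SR, f_lo=125, f_hi=4000)
        target = -6.0 * np.log2(centers / 1000.0)
        once = shape_spectrum(audio, centers, target)
        twice = shape_spectrum(once, centers, target)
        _, a = band_levels(once, centers)
        _, b = band_levels(twice, centers)
        assert np.allclose(a, b, atol=0.5)

    def test_unattainable_band_rejected(self):
        # band-limited noise with exactly zero energy below 500 Hz
        rng = np.random.default_rng(15)
        n = SR * 2
        spec = np.zeros(n // 2 + 1, dtype=complex)
        freqs = np.fft.rfftfreq(n, 1.0 / SR)
        band = (freqs >= 500) & (freqs <= 2000)
        spec[band] = rng.normal(size=band.sum()) + 1j * rng.normal(size=band.sum())
        audio = AudioSegment(samples=np.fft.irfft(spec, n=n), rate=SR)
        centers = third_octave_bands(SR, f_lo=125, f_hi=4000)
        with pytest.raises(ValueError, match="unattainable"):
            shape_spectrum(audio, centers, np.zeros_like(centers))


def _speech_like(duration_s=20.0, seed=8):
    """Noise with strong slow amplitude modulation (speech-like envelope)."""
    n = int(duration_s * SR)
    t = np.arange(n) / SR
    env = 0.55 + 0.45 * np.sin(2 * np.pi * 3.0 * t)
    return AudioSegment(samples=_noise(duration_s, seed) * env, rate=SR)


class TestSynthesizeStationary:
    def test_rejects_single_copy(self):
        with pytest.raises(ValueError):
            synthesize_stationary(_speech_like(), 1, seed=0)

    def test_reduces_modulation_depth(self):
        src = _speech_like()
        out = synthesize_stationary(src, 32, seed=1)
        assert envelope_modulation_depth_db(out) < envelope_modulation_depth_db(src)

    def test_preserves_long_term_spectrum_within_1db(self):
        src = _speech_like()
        out = synthesize_stationary(src, 32, seed=2)
        centers = third_octave_bands(SR, f_lo=125, f_hi=4000)
        _, a = band_levels(src, centers)
        _, b = band_levels(out, centers)
        assert np.max(np.abs(a - b)) < 1.0

    def test_seed_determinism(self):
        src = _speech_like()
        a = synthesize_stationary(src, 8, seed=3)
        b = synthesize_stationary(src, 8, seed=3)
        assert np.array_equal(a.samples, b.samples)


class TestRearrangeAndRms:
    def test_identity_permutation(self):
        audio = AudioSegment(samples=_noise(4.0, 9), rate=SR)
        out = rearrange_sections(audio, [1.0, 1.0, 2.0], permutation=[0, 1, 2])
        assert np.array_equal(out.samples, audio.samples)

    def test_swap_twice_recovers_input(self):
        audio = AudioSegment(samples=_noise(2.0, 10), rate=SR)
        once = rearrange_sections(audio, [1.0, 1.0], permutation=[1, 0])
        back = rearrange_sections(once, [1.0, 1.0], permutation=[1, 0])
        assert np.array_equal(back.samples, audio.samples)

    def test_multiset_preserved(self):
        audio = AudioSegment(samples=_noise(3.0, 11), rate=SR)
        out = rearrange_sections(audio, [1.0, 1.0, 1.0], seed=4)
        assert np.array_equal(np.sort(out.samples), np.sort(audio.samples))

    def test_bad_tiling_rejected(self):
        audio = AudioSegment(samples=_noise(3.0, 12), rate=SR)
        with pytest.raises(ValueError):
            rearrange_sections(audio, [1.0, 1.0], permutation=[0, 1])

    def test_rms_normalize(self):
        audio = AudioSegment(samples=_noise(1.0, 13), rate=SR)
        out = rms_normalize(audio, 0.25)
        assert out.rms == pytest.approx(0.25)
        half = AudioSegment(samples=audio.samples * 0.5, rate=SR)
        gain = rms_normalize(half, audio.rms).samples / half.samples
        assert np.allclose(gain, 2.0)
        with pytest.raises(ValueError):
            rms_normalize(AudioSegment(samples=np.zeros(100), rate=SR), 1.0)


def test_wav_round_trip(tmp_path):
    audio = AudioSegment(samples=_noise(0.5, 14), rate=SR)
    path = tmp_path / "x.wav"
    write_wav(audio, path)
    back = read_wav(path)
    assert back.rate == SR
    assert np.allclose(back.samples, audio.samples, atol=1e-6)
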