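"""Masker-construction signal processing.

Speech-like maskers for audiometry are built from speech recordings by a
small set of operations: detecting and shortening speech pauses (long
pauses let listeners "glimpse" too much, so pauses above 250 ms are cut
to 250 ms), shaping the long-term spectrum to a target such as the
international long-term average speech spectrum (ILTASS), rearranging
the 10/20-s sections of a source signal so it is not recognizable, and
synthesizing a stationary masker by superimposing many time-shifted
copies of a speech signal (which keeps the long-term spectrum but
flattens the envelope).  All levels are RMS-normalized digitally.

Audio is mono float64 at any sample rate; WAV I/O uses scipy.io.wavfile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile


@dataclass
class AudioSegment:
    samples: np.ndarray
    rate: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("audio must be mono")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples ** 2)))


@dataclass(frozen=True)
class PauseInterval:
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("pause end must be after its start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def read_wav(path) -> AudioSegment:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        raise ValueError("expected mono WAV")
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioSegment(samples=np.asarray(data, dtype=float), rate=int(rate))


def write_wav(audio: AudioSegment, path) -> None:
    wavfile.write(path, audio.rate, audio.samples.astype(np.float32))


# --------------------------------------------------------------------------

def detect_pauses(audio: AudioSegment, frame_ms: float = 10.0,
                  threshold_db_rel: float = -25.0,
                  min_pause_ms: float = 250.0) -> list[PauseInterval]:
    """Find speech pauses as runs of low-energy frames.

    A frame counts as pause material when its RMS is at least
    ``|threshold_db_rel|`` dB below the signal's long-term RMS; maximal
    runs of at least ``min_pause_ms`` are returned.  A silent signal is
    reported as one pause spanning the whole file.
    """
    if frame_ms <= 0:
        raise ValueError("frame length must be positive")
    x = audio.samples
    long_term = np.sqrt(np.mean(x ** 2))
    if long_term == 0:
        return [PauseInterval(0.0, audio.duration_s)]
    frame = max(1, int(round(frame_ms / 1000.0 * audio.rate)))
    n_frames = x.size // frame
    frames = x[:n_frames * frame].reshape(n_frames, frame)
    frame_rms = np.sqrt(np.mean(frames ** 2, axis=1))
    with np.errstate(divide="ignore"):
        rel_db = 20.0 * np.log10(np.where(frame_rms > 0, frame_rms, np.finfo(float).tiny)
                                 / long_term)
    quiet = rel_db <= threshold_db_rel
    pauses = []
    start = None
    for i, q in enumerate(list(quiet) + [False]):
        if q and start is None:
            start = i
        elif not q and start is not None:
            dur_ms = (i - start) * frame * 1000.0 / audio.rate
            if dur_ms >= min_pause_ms:
                pauses.append(PauseInterval(start * frame / audio.rate,
                                            i * frame / audio.rate))
            start = None
    return pauses


def shorten_pauses(audio: AudioSegment, pauses, max_pause_ms: float = 250.0,
                   crossfade_ms: float = 5.0) -> AudioSegment:
    """Cut every pause longer than ``max_pause_ms`` down to that length.

    The excess is excised symmetrically around the pause center, with a
    short linear crossfade at the splice; samples outside excised
    regions (and the crossfade ramps) are untouched.
    """
    pauses = sorted(pauses, key=lambda p: p.start_s)
    for a, b in zip(pauses, pauses[1:]):
        if b.start_s < a.end_s:
            raise ValueError("pauses overlap")
    x = audio.samples
    sr = audio.rate
    max_len = max_pause_ms / 1000.0
    fade = int(round(crossfade_ms / 1000.0 * sr))
    parts = []
    cursor = 0
    spliced = False
    for p in pauses:
        excess = int(round(max(0.0, p.duration_s - max_len) * sr))
        if excess <= 0:
            continue
        center = int(round((p.start_s + p.end_s) / 2.0 * sr))
        cut_a = center - excess // 2
        cut_b = cut_a + excess
        pre = x[cursor:cut_a]
        # overlap-blend inside the excised region so the output length is
        # exactly input minus the excess
        n = min(fade, excess, pre.size)
        if n > 0:
            ramp = np.linspace(0.0, 1.0, n)
            blend = pre[-n:] * (1.0 - ramp) + x[cut_b - n:cut_b] * ramp
            parts.append(pre[:-n])
            parts.append(blend)
        else:
            parts.append(pre)
        cursor = cut_b
        spliced = True
    parts.append(x[cursor:])
    if not spliced:
        return AudioSegment(samples=x.copy(), rate=sr)
    return AudioSegment(samples=np.concatenate(parts), rate=sr)


# --------------------------------------------------------------------------

def third_octave_bands(rate: int, f_lo: float = 100.0, f_hi: float | None = None):
    """Center frequencies of the third-octave bands inside [f_lo, Nyquist)."""
    f_hi = f_hi or rate / 2.0 / 2 ** (1 / 6)
    centers = []
    n = -30
    while True:
        fc = 1000.0 * 2.0 ** (n / 3.0)
        if fc > f_hi:
            break
        if fc >= f_lo:
            centers.append(fc)
        n += 1
    return np.array(centers)


def band_levels(audio: AudioSegment, centers=None) -> tuple[np.ndarray, np.ndarray]:
    """Long-term third-octave band levels in dB (re full scale power)."""
    centers = third_octave_bands(audio.rate) if centers is None else np.asarray(centers)
    spec = np.fft.rfft(audio.samples)
    power = np.abs(spec) ** 2 / audio.samples.size
    freqs = np.fft.rfftfreq(audio.samples.size, 1.0 / audio.rate)
    levels = np.empty(centers.size)
    for i, fc in enumerate(centers):
        lo, hi = fc / 2 ** (1 / 6), fc * 2 ** (1 / 6)
        mask = (freqs >= lo) & (freqs < hi)
        p = power[mask].sum()
        levels[i] = 10.0 * np.log10(p) if p > 0 else -np.inf
    return centers, levels


def shape_spectrum(audio: AudioSegment, target_centers, target_levels_db) -> AudioSegment:
    """Filter so the long-term third-octave spectrum matches the target.

    The per-band gain is target minus measured level; gains are
    interpolated over log-frequency and applied as a zero-phase FFT
    filter.  Raises when a target band has no energy in the input.
    Target levels may be given on any absolute scale — only band
    differences matter, and the output is re-normalized to the input
    RMS (shaping is level-preserving).
    """
    centers = np.asarray(target_centers, dtype=float)
    target = np.asarray(target_levels_db, dtype=float)
    _, measured = band_levels(audio, centers)
    # a band >120 dB below the strongest one is numerically empty
    empty = np.isinf(measured) | (measured < measured.max() - 120.0)
    if np.any(empty & np.isfinite(target)):
        bad = centers[empty & np.isfinite(target)]
        raise ValueError(f"no input energy in band(s) at {bad} Hz; target unattainable")
    out = audio
    # band gains are interpolated per FFT bin, so the realized band
    # average deviates slightly where the gain curve bends; one or two
    # correction passes bring every band within tolerance (and make the
    # operation idempotent)
    for _ in range(3):
        _, measured = band_levels(out, centers)
        gains_db = target - measured
        gains_db -= gains_db.mean()  # absolute level handled by RMS normalization
        if np.max(np.abs(gains_db)) < 0.1:
            break
        spec = np.fft.rfft(out.samples)
        freqs = np.fft.rfftfreq(out.samples.size, 1.0 / out.rate)
        safe = np.maximum(freqs, centers[0] / 4)
        gain_interp = np.interp(np.log(safe), np.log(centers), gains_db,
                                left=gains_db[0], right=gains_db[-1])
        shaped = np.fft.irfft(spec * 10.0 ** (gain_interp / 20.0),
                              n=out.samples.size)
        out = AudioSegment(samples=shaped, rate=out.rate)
    return rms_normalize(out, audio.rms)


def synthesize_stationary(audio: AudioSegment, n_superpositions: int,
                          seed) -> AudioSegment:
    """Stationary masker: sum of random circular time-shifts of a source.

    Keeps the source's long-term spectrum while the envelope modulation
    depth shrinks roughly as 1/sqrt(n).  RMS matches the source.
    """
    if n_superpositions < 2:
        raise ValueError("need at least 2 superpositions")
    rng = np.random.default_rng(seed)
    x = audio.samples
    acc = np.zeros_like(x)
    for _ in range(n_superpositions):
        acc += np.roll(x, int(rng.integers(x.size)))
    return rms_normalize(AudioSegment(samples=acc, rate=audio.rate), audio.rms)


def envelope_modulation_depth_db(audio: AudioSegment, frame_ms: float = 20.0) -> float:
    """SD of the frame-RMS envelope in dB — a simple modulation-depth index."""
    frame = max(1, int(round(frame_ms / 1000.0 * audio.rate)))
    n = audio.samples.size // frame
    frames = audio.samples[:n * frame].reshape(n, frame)
    env = np.sqrt(np.mean(frames ** 2, axis=1))
    env = env[env > 0]
    return float(np.std(20.0 * np.log10(env)))


def rearrange_sections(audio: AudioSegment, section_lengths_s,
                       permutation=None, seed=None) -> AudioSegment:
    """Permute the signal's sections (sample-exact within sections)."""
    lengths = [int(round(s * audio.rate)) for s in section_lengths_s]
    if sum(lengths) != audio.samples.size:
        raise ValueError("section lengths do not tile the signal")
    bounds = np.cumsum([0] + lengths)
    sections = [audio.samples[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    if permutation is None:
        permutation = np.random.default_rng(seed).permutation(len(sections))
    permutation = list(permutation)
    if sorted(permutation) != list(range(len(sections))):
        raise ValueError("not a permutation of the sections")
    return AudioSegment(samples=np.concatenate([sections[i] for i in permutation]),
                        rate=audio.rate)


def rms_normalize(audio: AudioSegment, target_rms: float) -> AudioSegment:
    """Scale so the RMS equals ``target_rms`` exactly."""
    rms = audio.rms
    if rms == 0:
        raise ValueError("cannot normalize a silent signal")
    return AudioSegment(samples=audio.samples * (target_rms / rms), rate=audio.rate)
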