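"""Masker construction: pause shortening, superposition, spectral shaping.

Builds a speech-like test signal (modulated noise), caps its pauses at
250 ms, synthesizes a stationary masker by superimposing 32 circular
time-shifts, and shapes white noise to a falling target spectrum.  The
printed numbers show what each operation changes: signal length (pause
excision), envelope modulation depth (superposition), spectral slope
(shaping).
"""

import numpy as np

from speechresp.dsp import (AudioSegment, band_levels, detect_pauses,
                            envelope_modulation_depth_db, shape_spectrum,
                            shorten_pauses, synthesize_stationary,
                            third_octave_bands)

SR = 16000
rng = np.random.default_rng(0)

# speech-like fixture: noise bursts separated by pauses of 600/300 ms
parts = []
for gap in (0.6, 0.3):
    parts.append(rng.normal(0, 0.1, int(1.0 * SR)))
    parts.append(np.zeros(int(gap * SR)))
parts.append(rng.normal(0, 0.1, int(1.0 * SR)))
speech = AudioSegment(samples=np.concatenate(parts), rate=SR)

pauses = detect_pauses(speech)
short = shorten_pauses(speech, pauses, max_pause_ms=250)
print(f"pauses found: {[f'{p.duration_s * 1000:.0f} ms' for p in pauses]}")
print(f"length {speech.duration_s:.2f} s -> {short.duration_s:.2f} s "
      "(only the excess over 250 ms is excised)")

env = 0.55 + 0.45 * np.sin(2 * np.pi * 3.0 * np.arange(SR * 20) / SR)
modulated = AudioSegment(samples=rng.normal(0, 0.1, SR * 20) * env, rate=SR)
stationary = synthesize_stationary(modulated, 32, seed=1)
print(f"modulation depth {envelope_modulation_depth_db(modulated):.1f} dB -> "
      f"{envelope_modulation_depth_db(stationary):.1f} dB after 32 superpositions")

white = AudioSegment(samples=rng.normal(0, 0.1, SR * 20), rate=SR)
centers = third_octave_bands(SR, f_lo=125, f_hi=4000)
target = -6.0 * np.log2(centers / 1000.0)       # -6 dB per octave
shaped = shape_spectrum(white, centers, target)
_, levels = band_levels(shaped, centers)
slope = np.polyfit(np.log2(centers), levels, 1)[0]
print(f"white noise shaped to -6 dB/octave: measured slope {slope:.2f} dB/octave")
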