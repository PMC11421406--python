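"""Verbal response time (VRT) and response speech rate (RSR).

VRT is the gap between the end of the presented sentence and the first
response word; it can be slightly negative when the listener starts
early (floor -150 ms).  The log transform 10*ln((VRT+0.15)/0.15) makes
the skewed VRT distribution workable in linear models.  RSR is words
per second over the response span, pauses included.
"""

from speechresp import ResponseAlignment, compute_rsr, compute_vrt, log_vrt, manual_convention

alignment = ResponseAlignment(
    trial_key=("NH01", 7, 3),
    tokens=[("Peter", 2.45, 0.45), ("sieht", 3.00, 0.42), ("zwei", 3.51, 0.36),
            ("alte", 3.93, 0.39), ("Autos", 4.38, 0.57)],
    sentence_end_s=2.0)

vrt = compute_vrt(alignment)
print(f"VRT          = {vrt * 1000:.0f} ms")
print(f"log-VRT      = {log_vrt(vrt):.2f}   (0 means VRT = 0 ms)")
print(f"RSR          = {compute_rsr(alignment):.2f} words/s")

early = ResponseAlignment(("NH01", 7, 4), tokens=[("Doris", 1.88, 0.45)],
                          sentence_end_s=2.0)
v = compute_vrt(early)
print(f"early start  = {v * 1000:.0f} ms (recognizer) "
      f"-> {manual_convention(v) * 1000:.0f} ms (examiner convention)")
print("The examiner clamps negative response times to zero; the recognizer")
print("resolves starts up to 150 ms before the sentence ends.")
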