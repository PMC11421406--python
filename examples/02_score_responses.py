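"""Word scoring and the rationalized arcsine (RAU) transform.

Scores a response against the presented five-word matrix sentence
(slot-wise: a word counts only in its own slot, <OOV> never matches),
computes a block score, and variance-stabilizes scores with RAU.
"""

from speechresp import OOV, ResponseAlignment, ScoreRecord, block_score, rau_transform, score_sentence

presented = ["Peter", "sieht", "zwei", "alte", "Autos"]
response = ResponseAlignment(
    trial_key=("NH01", 1, 1),
    tokens=[("Peter", 2.5, 0.4), ("sieht", 3.0, 0.4), (OOV, 3.5, 0.3),
            ("Autos", 3.9, 0.5)],
    sentence_end_s=2.0)

record = score_sentence(presented, response)
print(f"words correct: {record.n_correct} of 5  (the <OOV> token never matches)")

block = [ScoreRecord(("NH01", 1, i), n) for i, n in enumerate([5, 4, 3, 2, 1])]
print(f"block score:   {block_score(block):.0f}%  (15 of 25 presented words)")

for x in (0, 13, 25):
    print(f"RAU({x:2d}/25) = {rau_transform(x, 25):7.2f}")
print("RAU stretches the scale near 0% and 100%, where percent-correct")
print("scores are variance-compressed, so linear models behave better.")
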