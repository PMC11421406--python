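"""Rankit rank normalization and within-participant z-scores.

Categorical effort ratings (1-7) are not interval-scaled; the Rankit
transform maps rank r of n to the normal quantile at (r-0.5)/n.  Done
per participant, it removes each person's idiosyncratic use of the
scale.  Timing measures are z-scored within participant instead.
"""

import numpy as np

from speechresp import rankit, zscore_within

ratings = np.array([2, 2, 3, 5, 6, 6, 7, 4, 3, 2])
print("ratings:       ", ratings)
print("rankit (global):", np.round(rankit(ratings), 2))

# two participants using different parts of the scale for the same
# underlying effort profile
vals = np.array([1, 2, 3, 4, 5, 3, 4, 5, 6, 7], float)
keys = np.array(["lenient"] * 5 + ["strict"] * 5)
print("rankit (per participant):", np.round(rankit(vals, keys), 2))
print("  -> identical profiles once each person's scale use is removed")

z = zscore_within(vals, keys)
print("z within participant:    ", np.round(z, 2))
print("  -> mean 0 / SD 1 per participant; group offsets vanish")
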