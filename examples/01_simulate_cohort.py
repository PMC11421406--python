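"""Simulate a synthetic speech-audiometry cohort.

Builds a small study (4 listeners, 2 maskers, 5 SNRs re SRT, 5-sentence
blocks), simulates recognizer alignments and effort ratings, and injects
a missingness structure.  The printed counts show the design cardinality
(listeners x maskers x SNRs x sentences) and how many trials survive
with all channels present.
"""

from speechresp import CohortConfig, MissingnessPlan, inject_missingness, simulate_cohort

config = CohortConfig(
    n_nh=2, n_hi=2,
    maskers={"OLnoise": 2, "ISTS": 1},   # type 2 = stationary, 1 = fluctuating
    missingness=MissingnessPlan(n_unrecorded=1, n_no_response=2,
                                n_asr_only=3, n_manual_only=1),
)

cohort = simulate_cohort(config, seed=1)
cohort = inject_missingness(cohort, config.missingness, seed=1)

print(f"trials simulated:   {len(cohort.trials)}")
print(f"complete records:   {cohort.n_complete}")
print(f"blocks rated:       {len(cohort.ratings)}")
print(f"alignment tokens:   {sum(a.n_tokens for a in cohort.alignments)}")
first = cohort.alignments[0]
print(f"first response:     {[t[0] for t in first.tokens]}")
print("Each listener completes every masker x SNR block once; the complete")
print("count is the trial count minus the four injected missingness sets.")
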