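# Methods

This note documents the models behind `speechresp`, the choices made
where the design was genuinely open, and what the synthetic data can
and cannot show.

## Measures

**Word scoring.** Responses are scored slot-wise against the presented
five-word matrix sentence: a response token counts only for the slot it
belongs to (each of the 50 words belongs to exactly one slot, so the
assignment is unambiguous), each token is consumed at most once, and
the `<OOV>` marker never matches. Block scores are the percentage of
the 25 presented words repeated correctly. When a sentence's recording
is missing but the examiner scored the block live, the missing
recognizer score is filled with the mean examiner score of the block's
recorded sentences ("fill" semantics; an additive variant of the
correction would change block scores by the same amount in this
design — fill is the implemented reading, and the correction touches so
few trials that the choice is immaterial downstream).

**VRT.** First-token onset minus sentence end, tokens meaning matrix
words or `<OOV>`. The transform `L = 10·ln((VRT + 0.15)/0.15)` maps
the admissible range (−0.15 s, ∞) onto ℝ; its inverse
`VRT = 0.15·(e^{L/10} − 1)` is used by the generator. Values below
−0.149 s (one 30-ms recognizer grid step inside the −150 ms floor) are
clamped there with a warning so the transform stays finite. The
examiner convention `max(0, VRT)` is kept as a separate column.

**RSR.** Token count divided by the span from first-token onset to
last-token end, pauses included. `<OOV>` tokens count for both VRT and
RSR.

**Normalization.** Rankit uses mean ranks for ties (the natural choice
for 7-category ratings; no tie rule is mandated anywhere) and the
plotting position (r − 0.5)/n. Global scope ranks all 1215 block
ratings together; individual scope ranks each participant's 45 ratings.
Ratings are elicited once per block, so ranking operates on block-level
values. z-scores use the sample (n−1) SD.

**Aggregation.** One row per listener × masker type × SNR (270 for the
full design): mean over blocks for scores and rank-normalized effort,
median for raw effort, VRT and RSR, mean for z-scored measures. RAU is
computed on pooled cell counts (x of n words) because the transform is
defined on counts; a flag selects the averaged-percentage variant.

## Statistics

**ICC.** Agreement between the recognizer and examiner channels is
ICC(A,1): single-measure absolute agreement from the two-way
(targets × raters) mean squares,
`(MS_R − MS_E)/(MS_R + MS_E + (2/n)(MS_C − MS_E))` for two raters.
Single measures is the conservative choice when the report does not
specify single vs. average.

**Stepwise regression.** Forward selection with entry at p ≤ .05 and
removal at p ≥ .10 — the defaults of the commercial package such
analyses typically use; both are arguments. Every candidate is
reported: predictors that never enter are shown with the coefficient
they would take if added to the final model (flagged `entered=False`),
which reproduces the familiar results-table shape where rejected
predictors still carry a coefficient and p-value. Standardized betas
are `b·SD(x)/SD(y)`; Durbin–Watson is computed on residuals in row
order (NaN when residuals are identically zero, as in noiseless
round-trip checks — the standalone `durbin_watson` raises instead).
No interaction terms are fitted: the masker-type-dependent slopes seen
in the data appear here only through the narrative direction checks,
since the target analysis reports main effects only.

**Collinearity.** Pairwise |r| with a 0.7 flag threshold; the pipeline
never co-enters SNR and effort ratings (they are strongly correlated
by construction), mirroring the replacement of SNR by SR-LE in the
score-on-effort model.

## The synthetic cohort

The generator's defaults are the study conditions, not tuning knobs.

- **Design**: 15 NH + 12 HI listeners; 9 maskers (OLnoise, IFnoise
  stationary; ICRA5-250, ISTS, IFFM, NFIMG, NFIMM, NFFMG, NFFMM
  fluctuating); SNR re SRT ∈ {0, 3, 6, 9, 12} dB; 45 blocks × 5
  sentences; block order randomized per listener.
- **SRTs**: stationary-masker group means −7.5/−8.5 dB SNR (NH,
  OLnoise/IFnoise) and −5.1/−5.5 dB SNR (HI); fluctuating maskers sit
  12 dB (NH) or 6 dB (HI) below the stationary mean (release from
  masking by dip listening). Between-listener SD 1.5 dB and per-masker
  jitter 0.5 dB are placeholders: within-group spreads are published
  only as boxplots, and 1–2 dB is the typical matrix-test
  between-listener spread. Jitter is bounded so stationary SRTs exceed
  fluctuating ones for every listener.
- **Psychometric functions**: word correctness is Bernoulli with
  `p = 1/(1 + e^{−4·s·snr})`, i.e. p = 0.5 at the SRT by definition
  and slope s at the midpoint. Slopes default to 15 %/dB (stationary)
  and 7 %/dB (fluctuating) — not printed in the source; chosen once
  from matrix-test literature, consistent with the qualitative
  "steeper for stationary" observation. Words are independent within a
  sentence (the simplest model compatible with word scoring; real
  responses have correlated errors, which inflates block-score
  variance relative to this model).
- **Effort**: a latent effort value, linear in SNR (−0.30/dB) and
  masker type (−1.0 for stationary) with N(0, 0.8) residual, is cut at
  6 thresholds (defaults equally spaced 1.5…6.5, shifted per listener
  by N(0, 0.5)) into the 7 categories — the per-listener shift emulates
  different interpretations of the rating scale.
- **Timing**: log-VRT is linear in SNR (−0.7/dB) and masker type
  (+2.5 for fluctuating) with an HI intercept offset (+4) and a
  per-listener pace offset; raw VRT comes from the inverse transform.
  RSR is linear in SNR (+0.04/dB) and type (+0.15 stationary), base
  2.8 wps (NH) / 2.2 wps (HI), truncated below at 0.3 wps. These
  coefficients are not published as generative truth anywhere; they
  were fixed once to produce response times of roughly 0.2–1.5 s and
  rates of 2–3 words/s with the observed effect directions.
- **Alignments** are symbolic: token onsets/durations on the 30-ms
  recognizer grid, first onset at sentence end + VRT, span =
  n_tokens/RSR. Missed words become, with probability 0.5, either an
  `<OOV>` token or a wrong same-slot word (which never scores). Every
  simulated response carries at least one token, so the only empty
  responses are the injected no-response trials.
- **Missingness**: 3 unrecorded (at most one per block, so the block
  correction stays defined), 22 no-response, 52 recognizer-only, 6
  examiner-only — assigned uniformly at random over trials; which
  conditions were affected in reality is not reported.
- **Determinism**: one master seed; children are derived with
  `numpy.random.SeedSequence((seed, 1)).spawn()` per listener, then
  per block, then per sentence. Identical seeds give bit-identical
  cohorts.

## Latent-linear recovery experiments

The regression analysis is validated by parameter recovery: the five
published models (RAU score, rank-normalized effort, score-on-effort,
z-log-VRT, z-RSR) serve as generating truth over the realized 270-cell
design, with the residual SD calibrated from the published adjusted R²
via `σ² = Var(lp)·(1 − R²)/R²` computed on the realized linear
predictor. This calibration is independently corroborated: it
reproduces the published coefficient standard errors (e.g., 0.157 for
the SNR slope of the score model) without any fitting. For the
score-on-effort model the effort covariate is itself generated from
the effort model's truth, preserving its correlation with masker type.
Intercepts are not published; defaults center predictions (≈50 RAU at
SRT, mid-scale effort) and slope recovery is intercept-invariant.
`scripts/acceptance.py` runs 100 Monte-Carlo replicates per model
(~20 s total) and reports median recovered coefficients; the test
suite additionally checks that per-seed estimates fall within two
Monte-Carlo SDs of the truth in ≥90% of seeds and that true-zero
effects (group in the z-scored models) rarely enter.

## Masker DSP

Pause detection uses 10-ms frame RMS with a −25 dB threshold relative
to long-term RMS and a 250-ms minimum run — none of this is specified
by the procedures being reproduced, which presume pause intervals as
given; all three values are arguments. Shortening excises the excess
symmetrically around the pause center with a 5-ms crossfade blended
inside the excised region, so the output length is exactly the input
minus Σ max(0, pause − cap) and no sample outside pause regions
changes. Spectral shaping applies per-third-octave gains interpolated
over log-frequency as a zero-phase FFT filter, with up to three
correction passes (per-bin interpolation misallocates band averages
where the gain curve bends; iteration brings every band within ±1 dB
and makes the operation idempotent); absolute level is delegated to
RMS normalization, so targets matter only up to a common offset.
Stationary synthesis sums n seeded circular time-shifts, preserving
the long-term spectrum while envelope modulation shrinks ≈ 1/√n.
Target spectra (e.g., ILTASS) are input files, not constants.

## Scope and limitations

- The recognizer itself is out of scope; the pipeline consumes its
  output format (CTM) and the generator simulates it. Adaptive SRT
  tracking is likewise not simulated — SRTs are drawn from group
  distributions.
- Passing tests on synthetic cohorts show the *pipeline* is unbiased
  and faithful to the stated transforms; they cannot show that the
  generative defaults match human behavior (slopes, effort noise,
  timing coefficients are plausible but unverifiable without data).
- The full-pipeline regressions on the default psychometric cohort
  reproduce effect directions and rough magnitudes, not the published
  coefficients — those are reproduced by the latent-linear recovery
  experiments, where they are the generating truth.
- Problem sizes: the default cohort (6075 sentences) runs in ~3 s;
  the acceptance experiment uses 100 replicates per model, at which
  the Monte-Carlo SE of each reported median is well below the last
  printed digit of the corresponding coefficient (except the
  masker-type coefficient of the score model, whose printed precision
  exceeds what 100 replicates resolve; its median still lands within
  ~1% of the truth).
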