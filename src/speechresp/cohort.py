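"""Synthetic cohort generator for matrix-test speech audiometry.

The study design emulated here: two listener groups (15 normal-hearing,
NH, coded 1; 12 hearing-impaired, HI, coded 2) each complete 45 blocks
of five matrix sentences — every combination of 9 maskers (2 stationary,
coded masker type 2; 7 fluctuating, coded 1) and 5 SNRs fixed at the
listener's individually measured speech-recognition threshold (SRT)
plus 0, 3, 6, 9 or 12 dB.  That is 225 sentences per listener and 6075
in the full cohort.  After each block the listener rates perceived
listening effort on a 7-category scale; the verbal response to every
sentence is recorded and time-aligned by a recognizer on a 30-ms grid.

Two generative modes are provided:

``psychometric``
    Word correctness is Bernoulli with probability from a logistic
    psychometric function centered at the SRT (p = 0.5 at SNR re SRT =
    0 dB) with a masker-type-specific slope — steeper for stationary
    than for fluctuating maskers, as observed for matrix tests.
    Effort, response time and speech rate come from latent linear
    models in SNR and masker type with listener-specific offsets.

``latent_linear``
    Block-level outcomes are drawn directly from configurable linear
    models (coefficients + Gaussian residual) in SNR, masker type and
    group.  This is the generating structure of the study's regression
    analysis and is used for coefficient-recovery experiments: the
    printed regression coefficients serve as ground truth and the
    residual SD is calibrated from the reported adjusted R² via
    sigma² = Var(linear predictor) · (1 − R²) / R².

Randomness: one master seed; child generators are derived
deterministically per listener and per block with
``numpy.random.SeedSequence(master_seed).spawn()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .io import ResponseAlignment, TIME_RESOLUTION_S
from .vocabulary import OOV, Vocabulary, DEFAULT_VOCABULARY

FLUCTUATING, STATIONARY = 1, 2
NH, HI = "NH", "HI"
GROUP_CODE = {NH: 1, HI: 2}

#: the study's nine maskers and their types
DEFAULT_MASKERS = {
    "ICRA5-250": FLUCTUATING,
    "ISTS": FLUCTUATING,
    "IFFM": FLUCTUATING,
    "NFIMG": FLUCTUATING,
    "NFIMM": FLUCTUATING,
    "NFFMG": FLUCTUATING,
    "NFFMM": FLUCTUATING,
    "OLnoise": STATIONARY,
    "IFnoise": STATIONARY,
}

DEFAULT_SNR_OFFSETS = (0.0, 3.0, 6.0, 9.0, 12.0)


# --------------------------------------------------------------------------
# configuration

@dataclass
class MissingnessPlan:
    """Counts of the four incomplete-record categories to inject."""

    n_unrecorded: int = 3
    n_no_response: int = 22
    n_asr_only: int = 52
    n_manual_only: int = 6

    def __post_init__(self):
        if min(self.n_unrecorded, self.n_no_response,
               self.n_asr_only, self.n_manual_only) < 0:
            raise ValueError("missingness counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_unrecorded + self.n_no_response + self.n_asr_only + self.n_manual_only


@dataclass
class CohortConfig:
    """All generative knobs of the synthetic cohort.

    SRT means for the stationary maskers default to the study's group
    means (OLnoise NH -7.5 / HI -5.1 dB SNR; IFnoise NH -8.5 / HI -5.5);
    fluctuating-masker SRTs default to the stationary mean minus the
    group's release from masking (12 dB NH, 6 dB HI).  Psychometric
    slopes default to 15 %/dB (stationary) and 7 %/dB (fluctuating).
    """

    n_nh: int = 15
    n_hi: int = 12
    maskers: dict = field(default_factory=lambda: dict(DEFAULT_MASKERS))
    snr_offsets: tuple = DEFAULT_SNR_OFFSETS
    sentences_per_block: int = 5

    # SRT generation (dB SNR)
    srt_stationary_mean: dict = field(default_factory=lambda: {
        (NH, "OLnoise"): -7.5, (NH, "IFnoise"): -8.5,
        (HI, "OLnoise"): -5.1, (HI, "IFnoise"): -5.5,
    })
    masking_release_db: dict = field(default_factory=lambda: {NH: 12.0, HI: 6.0})
    between_listener_srt_sd: float = 1.5
    per_masker_srt_jitter_sd: float = 0.5

    # psychometric slopes, proportion correct per dB at the 50% point
    slope_per_type: dict = field(default_factory=lambda: {STATIONARY: 0.15, FLUCTUATING: 0.07})

    # latent listening-effort model (7-category scale)
    srle_intercept: float = 5.5
    srle_snr_coef: float = -0.30
    srle_stationary_offset: float = -1.0
    srle_residual_sd: float = 0.8
    srle_threshold_base: tuple = (1.5, 2.5, 3.5, 4.5, 5.5, 6.5)
    srle_threshold_shift_sd: float = 0.5

    # verbal response time on the log-VRT scale (10*ln((VRT+0.15)/0.15))
    vrt_intercept: float = 18.0
    vrt_hi_offset: float = 4.0
    vrt_snr_coef: float = -0.7
    vrt_fluctuating_offset: float = 2.5
    vrt_residual_sd: float = 3.0
    vrt_pace_sd: float = 3.0

    # response speech rate, words per second
    rsr_base: float = 2.8
    rsr_hi_offset: float = -0.6
    rsr_snr_coef: float = 0.04
    rsr_stationary_offset: float = 0.15
    rsr_residual_sd: float = 0.25
    rsr_pace_sd: float = 0.2
    rsr_min: float = 0.3

    # hearing level at 500 Hz, dB HL (used only by presentation_level)
    hl500_nh_range: tuple = (0.0, 15.0)
    hl500_hi_mean: float = 40.0
    hl500_hi_sd: float = 10.0

    # block-score linear model for latent_linear mode, percent scale
    score_intercept: float = 50.0
    score_snr_coef: float = 4.0
    score_stationary_offset: float = 13.0
    score_group_offset: float = -1.0
    score_residual_sd: float = 5.0

    # response-simulation details
    substitution_rate: float = 0.5   # missed word -> some audible substitution
    oov_share: float = 0.5           # share of substitutions that are out-of-vocabulary

    missingness: MissingnessPlan = field(default_factory=MissingnessPlan)

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        """Load a configuration from a YAML or JSON document."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if "missingness" in raw and isinstance(raw["missingness"], dict):
            raw["missingness"] = MissingnessPlan(**raw["missingness"])
        for key in ("snr_offsets", "srle_threshold_base", "hl500_nh_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "srt_stationary_mean" in raw:
            raw["srt_stationary_mean"] = {
                (k.split("/")[0], k.split("/")[1]): v
                for k, v in raw["srt_stationary_mean"].items()
            }
        return cls(**raw)

    def to_file(self, path) -> None:
        raw = asdict(self)
        raw["srt_stationary_mean"] = {
            f"{g}/{m}": v for (g, m), v in self.srt_stationary_mean.items()
        }
        raw["snr_offsets"] = list(self.snr_offsets)
        raw["srle_threshold_base"] = list(self.srle_threshold_base)
        raw["hl500_nh_range"] = list(self.hl500_nh_range)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, allow_unicode=True, sort_keys=False)


# --------------------------------------------------------------------------
# listeners

@dataclass
class VirtualListener:
    listener_id: str
    group: str                      # "NH" or "HI"
    hl500: float                    # dB HL at 500 Hz
    srt_per_masker: dict            # masker_id -> dB SNR
    slope_per_type: dict            # masker type -> proportion/dB at the 50% point
    srle_thresholds: np.ndarray     # 6 ordered latent cutpoints
    vrt_params: tuple               # (intercept, snr_coef, fluct_offset, residual_sd)
    rsr_params: tuple               # (base_rate, snr_coef, stat_offset, residual_sd)
    pace_offset: tuple              # (log-VRT shift, RSR shift)

    def __post_init__(self):
        t = np.asarray(self.srle_thresholds, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("srle_thresholds must be strictly increasing")
        if self.slope_per_type[STATIONARY] <= self.slope_per_type[FLUCTUATING]:
            raise ValueError("stationary psychometric slope must exceed fluctuating")


def presentation_level(hl500: float) -> float:
    """Masker presentation level in dB SPL for a hearing loss at 500 Hz.

    65 dB SPL plus half the individual 500-Hz hearing loss, capped at 80.
    """
    if hl500 < 0:
        raise ValueError("hearing level must be >= 0 dB HL")
    return min(65.0 + hl500 / 2.0, 80.0)


def draw_listener(group: str, seed, config: CohortConfig | None = None,
                  listener_id: str | None = None) -> VirtualListener:
    """Draw one virtual listener's generative parameters."""
    if group not in (NH, HI):
        raise ValueError(f"unknown group {group!r}; expected 'NH' or 'HI'")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    listener_id = listener_id or f"{group}{rng.integers(1_000_000):06d}"

    offset = rng.normal(0.0, cfg.between_listener_srt_sd)
    stat_means = {m: cfg.srt_stationary_mean[(group, m)]
                  for m, t in cfg.maskers.items() if t == STATIONARY}
    stat_base = float(np.mean(list(stat_means.values()))) if stat_means else 0.0
    release = cfg.masking_release_db[group]
    srt = {}
    for masker, mtype in cfg.maskers.items():
        jitter = rng.normal(0.0, cfg.per_masker_srt_jitter_sd)
        if mtype == STATIONARY:
            srt[masker] = stat_means.get(masker, stat_base) + offset + jitter
        else:
            # release from masking by dip listening: fluctuating SRTs sit
            # well below the stationary ones for every listener
            jitter = float(np.clip(jitter, -release / 2 + 0.5, release / 2 - 0.5))
            srt[masker] = stat_base - release + offset + jitter

    if group == NH:
        hl500 = float(rng.uniform(*cfg.hl500_nh_range))
    else:
        hl500 = float(np.clip(rng.normal(cfg.hl500_hi_mean, cfg.hl500_hi_sd), 0.0, 80.0))

    thresholds = np.asarray(cfg.srle_threshold_base, dtype=float) \
        + rng.normal(0.0, cfg.srle_threshold_shift_sd)

    vrt_intercept = cfg.vrt_intercept + (cfg.vrt_hi_offset if group == HI else 0.0)
    rsr_base = cfg.rsr_base + (cfg.rsr_hi_offset if group == HI else 0.0)
    pace = (float(rng.normal(0.0, cfg.vrt_pace_sd)), float(rng.normal(0.0, cfg.rsr_pace_sd)))

    return VirtualListener(
        listener_id=listener_id,
        group=group,
        hl500=hl500,
        srt_per_masker=srt,
        slope_per_type=dict(cfg.slope_per_type),
        srle_thresholds=thresholds,
        vrt_params=(vrt_intercept, cfg.vrt_snr_coef, cfg.vrt_fluctuating_offset,
                    cfg.vrt_residual_sd),
        rsr_params=(rsr_base, cfg.rsr_snr_coef, cfg.rsr_stationary_offset,
                    cfg.rsr_residual_sd),
        pace_offset=pace,
    )


# --------------------------------------------------------------------------
# design

def build_design(n_nh: int, n_hi: int, maskers: dict, snr_offsets,
                 sentences_per_block: int, seed,
                 vocabulary: Vocabulary = DEFAULT_VOCABULARY) -> pd.DataFrame:
    """The full trial table: every masker x SNR block for every listener.

    Block order is randomized per listener; sentences are drawn
    uniformly from the 10x5 word matrix.  Row count is exactly
    (n_nh + n_hi) * |maskers| * |snr_offsets| * sentences_per_block.
    """
    if not maskers:
        raise ValueError("masker list must not be empty")
    if n_nh + n_hi <= 0:
        raise ValueError("need at least one participant")
    ss = np.random.SeedSequence(seed)
    listener_seeds = ss.spawn(n_nh + n_hi)
    groups = [NH] * n_nh + [HI] * n_hi
    rows = []
    for idx, (group, lseed) in enumerate(zip(groups, listener_seeds), start=1):
        rng = np.random.default_rng(lseed)
        listener_id = f"{group}{idx:02d}"
        conditions = [(m, t, s) for m, t in maskers.items() for s in snr_offsets]
        order = rng.permutation(len(conditions))
        for block_id, cond_idx in enumerate(order, start=1):
            masker, mtype, snr = conditions[cond_idx]
            for sent_idx in range(1, sentences_per_block + 1):
                sentence = " ".join(vocabulary.matrix[slot][rng.integers(10)]
                                    for slot in range(5))
                # per-sentence recording: 0.5 s masker lead + ~2.25 s sentence,
                # quantized to the recognizer's 30-ms grid
                end = 2.75 + float(rng.integers(0, 11)) * TIME_RESOLUTION_S
                rows.append({
                    "listener_id": listener_id,
                    "group": GROUP_CODE[group],
                    "masker_id": masker,
                    "masker_type": int(mtype),
                    "snr_re_srt": float(snr),
                    "block_id": block_id,
                    "sentence_index": sent_idx,
                    "sentence": sentence,
                    "sentence_end_s": round(end, 2),
                })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# per-block outcome simulation

def _psychometric_p(snr_re_srt: float, slope: float) -> float:
    """Logistic psychometric function: p = 0.5 at SNR re SRT = 0, slope at midpoint."""
    return 1.0 / (1.0 + np.exp(-4.0 * slope * snr_re_srt))


def simulate_block(listener: VirtualListener, trials: pd.DataFrame, mode: str,
                   seed, config: CohortConfig | None = None):
    """Simulate one block's outcomes.

    Returns ``(correctness, srle, vrts, rsrs)``: a list of per-sentence
    boolean word-correctness arrays, the block's 7-category effort
    rating, and per-sentence raw VRT (s) and RSR (words/s).
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    if mode not in ("psychometric", "latent_linear"):
        raise ValueError(f"unknown mode {mode!r}")
    mtype = int(trials["masker_type"].iloc[0])
    snr = float(trials["snr_re_srt"].iloc[0])
    group_code = int(trials["group"].iloc[0])
    n_sent = len(trials)

    if mode == "psychometric":
        p = _psychometric_p(snr, listener.slope_per_type[mtype])
        correctness = [rng.random(5) < p for _ in range(n_sent)]
    else:
        # block-level score drawn directly from a linear model in SNR,
        # masker type and group, then spread evenly over the words
        pct = (cfg.score_intercept + cfg.score_snr_coef * snr
               + cfg.score_stationary_offset * (mtype - 1)
               + cfg.score_group_offset * (group_code - 1)
               + rng.normal(0.0, cfg.score_residual_sd))
        total = int(round(np.clip(pct, 0.0, 100.0) / 100.0 * 5 * n_sent))
        base, rem = divmod(total, n_sent)
        correctness = []
        for i in range(n_sent):
            k = base + (1 if i < rem else 0)
            mask = np.zeros(5, dtype=bool)
            mask[rng.permutation(5)[:k]] = True
            correctness.append(mask)

    effort = (cfg.srle_intercept + cfg.srle_snr_coef * snr
              + cfg.srle_stationary_offset * (mtype == STATIONARY)
              + rng.normal(0.0, cfg.srle_residual_sd))
    srle = int(1 + np.searchsorted(listener.srle_thresholds, effort))

    b0, b_snr, b_fluct, sd = listener.vrt_params
    vrts = []
    for _ in range(n_sent):
        log_v = (b0 + b_snr * snr + b_fluct * (mtype == FLUCTUATING)
                 + listener.pace_offset[0] + rng.normal(0.0, sd))
        vrts.append(0.15 * (np.exp(log_v / 10.0) - 1.0))

    r0, r_snr, r_stat, rsd = listener.rsr_params
    rsrs = []
    for _ in range(n_sent):
        rate = (r0 + r_snr * snr + r_stat * (mtype == STATIONARY)
                + listener.pace_offset[1] + rng.normal(0.0, rsd))
        rsrs.append(max(cfg.rsr_min, rate))
    return correctness, srle, vrts, rsrs


def simulate_alignment(sentence, n_correct_mask, vrt_s: float, rsr_wps: float,
                       seed, config: CohortConfig | None = None,
                       sentence_end_s: float = 0.0, trial_key=None,
                       vocabulary: Vocabulary = DEFAULT_VOCABULARY,
                       min_tokens: int = 0) -> ResponseAlignment:
    """Symbolic recognizer output for one response, on the 30-ms grid.

    Correct slots yield their presented word; missed slots yield, with
    probability ``substitution_rate``, either an out-of-vocabulary token
    or a wrong same-slot word.  The first token starts ``vrt_s`` after
    the sentence end and the token span is ``n_tokens / rsr_wps``.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    words = sentence.split() if isinstance(sentence, str) else list(sentence)
    if np.isscalar(n_correct_mask):
        n_correct = int(n_correct_mask)
        if not 0 <= n_correct <= 5:
            raise ValueError("n_correct must be in 0..5")
        mask = np.zeros(5, dtype=bool)
        mask[:n_correct] = True
    else:
        mask = np.asarray(n_correct_mask, dtype=bool)

    tokens = []
    for slot, (word, ok) in enumerate(zip(words, mask)):
        if ok:
            tokens.append(word)
        elif rng.random() < cfg.substitution_rate:
            if rng.random() < cfg.oov_share:
                tokens.append(OOV)
            else:
                alternatives = [w for w in vocabulary.matrix[slot] if w != word]
                tokens.append(alternatives[rng.integers(len(alternatives))])
    while len(tokens) < min_tokens:
        # the listener vocalized something even if nothing was recognized
        tokens.append(OOV)
    if not tokens:
        return ResponseAlignment(trial_key=trial_key or ("", 0, 0), tokens=[],
                                 sentence_end_s=sentence_end_s)
    if rsr_wps <= 0:
        raise ValueError("RSR must be positive when the response has tokens")

    grid = TIME_RESOLUTION_S
    onset0 = round((sentence_end_s + vrt_s) / grid) * grid
    if onset0 < 0:
        onset0 = 0.0
    span = len(tokens) / rsr_wps
    # equal word slots across the span; each word occupies ~80% of its slot
    slot_len = span / len(tokens)
    timed = []
    for i, tok in enumerate(tokens):
        onset = round((onset0 + i * slot_len) / grid) * grid
        dur = max(grid, round(slot_len * 0.8 / grid) * grid)
        if i == len(tokens) - 1:
            # pin the final token's end to the span (grid-quantized)
            end = round((onset0 + span) / grid) * grid
            dur = max(grid, round(end - onset, 10))
        timed.append((tok, round(onset, 10), round(dur, 10)))
    return ResponseAlignment(trial_key=trial_key or ("", 0, 0), tokens=timed,
                             sentence_end_s=sentence_end_s)


# --------------------------------------------------------------------------
# whole-cohort simulation

@dataclass
class Cohort:
    """A simulated study: trial table, recognizer alignments, the
    examiner's manual channel, and block-level effort ratings.

    ``trials`` carries the missingness flags: ``recorded`` (a recording
    exists), ``manual_response`` (the examiner logged a response) and
    ``complete`` (all channels present).  ``manual_scores`` has one row
    per trial with the examiner's word count (NaN when the examiner
    logged "no response").
    """

    trials: pd.DataFrame
    alignments: list
    manual_scores: pd.DataFrame
    ratings: pd.DataFrame
    listeners: list
    config: CohortConfig

    @property
    def n_complete(self) -> int:
        return int(self.trials["complete"].sum())


def simulate_cohort(config: CohortConfig | None = None, seed=0,
                    mode: str = "psychometric",
                    vocabulary: Vocabulary = DEFAULT_VOCABULARY) -> Cohort:
    """Generate the full synthetic study in one call (no missingness)."""
    cfg = config or CohortConfig()
    trials = build_design(cfg.n_nh, cfg.n_hi, cfg.maskers, cfg.snr_offsets,
                          cfg.sentences_per_block, seed, vocabulary)
    # seed derivation: SeedSequence((seed, 1)) yields one child per
    # listener; each child spawns one grandchild per block, and each
    # block seed one per sentence
    listener_seeds = np.random.SeedSequence((seed, 1)).spawn(cfg.n_nh + cfg.n_hi)

    listeners = []
    alignments = []
    manual_rows = []
    rating_rows = []
    for lidx, (listener_id, ltrials) in enumerate(trials.groupby("listener_id", sort=True)):
        group = NH if int(ltrials["group"].iloc[0]) == 1 else HI
        lseed = listener_seeds[lidx]
        listener = draw_listener(group, lseed, cfg, listener_id=listener_id)
        listeners.append(listener)
        block_seeds = lseed.spawn(ltrials["block_id"].nunique())
        for bidx, (block_id, btrials) in enumerate(ltrials.groupby("block_id", sort=True)):
            bseed = block_seeds[bidx]
            correctness, srle, vrts, rsrs = simulate_block(
                listener, btrials, mode, bseed, cfg)
            rating_rows.append({"listener_id": listener_id, "block_id": block_id,
                                "srle": srle})
            sent_seeds = bseed.spawn(len(btrials))
            for j, (_, trow) in enumerate(btrials.iterrows()):
                key = (listener_id, int(block_id), int(trow["sentence_index"]))
                ali = simulate_alignment(
                    trow["sentence"], correctness[j], vrts[j], rsrs[j],
                    sent_seeds[j], cfg, sentence_end_s=trow["sentence_end_s"],
                    trial_key=key, vocabulary=vocabulary, min_tokens=1)
                alignments.append(ali)
                manual_rows.append({
                    "listener_id": listener_id, "block_id": int(block_id),
                    "sentence_index": int(trow["sentence_index"]),
                    "n_correct": int(np.sum(correctness[j])),
                })
    trials = trials.assign(recorded=True, manual_response=True, asr_empty=False)
    manual = pd.DataFrame(manual_rows)
    ratings = pd.DataFrame(rating_rows)
    cohort = Cohort(trials=trials, alignments=alignments, manual_scores=manual,
                    ratings=ratings, listeners=listeners, config=cfg)
    _mark_complete(cohort)
    return cohort


def _mark_complete(cohort: Cohort) -> None:
    empty = {a.trial_key for a in cohort.alignments if a.n_tokens == 0}
    present = {a.trial_key for a in cohort.alignments}
    keys = list(zip(cohort.trials["listener_id"],
                    cohort.trials["block_id"], cohort.trials["sentence_index"]))
    cohort.trials["asr_empty"] = [k in empty or k not in present for k in keys]
    cohort.trials["complete"] = (cohort.trials["recorded"]
                                 & cohort.trials["manual_response"]
                                 & ~cohort.trials["asr_empty"])


def inject_missingness(cohort: Cohort, plan: MissingnessPlan | None = None,
                       seed=0) -> Cohort:
    """Impose the study's missingness structure on a simulated cohort.

    Four disjoint trial sets are drawn uniformly at random: unrecorded
    sentences (no recording, so no recognizer output; at most one per
    block so the block correction stays possible), no-response trials
    (both channels empty), recognizer-only trials (the examiner logged
    "no response" but the recognizer emitted at least one token), and
    manual-only trials (recognizer empty, examiner score retained).
    """
    plan = plan or cohort.config.missingness
    if plan.total > len(cohort.trials):
        raise ValueError("missingness counts exceed the number of trials")
    rng = np.random.default_rng(seed)
    trials = cohort.trials.copy()
    manual = cohort.manual_scores.copy()
    manual["n_correct"] = manual["n_correct"].astype(float)
    ali_by_key = {a.trial_key: a for a in cohort.alignments}
    keys = [(l, int(b), int(s)) for l, b, s in
            zip(trials["listener_id"], trials["block_id"], trials["sentence_index"])]
    order = rng.permutation(len(keys))
    taken: set = set()
    taken_blocks: set = set()

    def _draw(n, block_unique=False):
        chosen = []
        for i in order:
            if len(chosen) == n:
                break
            k = keys[i]
            if k in taken:
                continue
            if block_unique and (k[0], k[1]) in taken_blocks:
                continue
            chosen.append(k)
            taken.add(k)
            if block_unique:
                taken_blocks.add((k[0], k[1]))
        if len(chosen) < n:
            raise ValueError("not enough trials left for the missingness plan")
        return chosen

    unrecorded = set(_draw(plan.n_unrecorded, block_unique=True))
    no_response = set(_draw(plan.n_no_response))
    asr_only = set(_draw(plan.n_asr_only))
    manual_only = set(_draw(plan.n_manual_only))

    midx = manual.set_index(["listener_id", "block_id", "sentence_index"])
    new_alignments = []
    for ali in cohort.alignments:
        k = ali.trial_key
        if k in unrecorded or k in manual_only:
            new_alignments.append(ResponseAlignment(trial_key=k, tokens=[],
                                                    sentence_end_s=ali.sentence_end_s))
        elif k in no_response:
            new_alignments.append(ResponseAlignment(trial_key=k, tokens=[],
                                                    sentence_end_s=ali.sentence_end_s))
            midx.loc[k, "n_correct"] = np.nan
        elif k in asr_only:
            if ali.n_tokens == 0:
                # the recognizer "detected at least one word" in these
                # trials: give it a lone out-of-vocabulary token
                onset = round(ali.sentence_end_s / TIME_RESOLUTION_S) * TIME_RESOLUTION_S + 0.45
                ali = ResponseAlignment(trial_key=k,
                                        tokens=[(OOV, round(onset, 2), 0.45)],
                                        sentence_end_s=ali.sentence_end_s)
            midx.loc[k, "n_correct"] = np.nan
            new_alignments.append(ali)
        else:
            new_alignments.append(ali)
    manual = midx.reset_index()

    trials["recorded"] = [k not in unrecorded for k in keys]
    trials["manual_response"] = [k not in (no_response | asr_only) for k in keys]
    out = Cohort(trials=trials, alignments=new_alignments, manual_scores=manual,
                 ratings=cohort.ratings.copy(), listeners=cohort.listeners,
                 config=cohort.config)
    _mark_complete(out)
    # manual-only and no-response trials are empty on the recognizer
    # channel but the recording exists; completeness additionally
    # requires the examiner's channel
    out.trials.loc[[k in manual_only for k in keys], "complete"] = False
    return out


# --------------------------------------------------------------------------
# latent-linear coefficient-recovery experiments (the study's regression models)

@dataclass(frozen=True)
class LatentLinearModel:
    """One regression model of the study's analysis, used as generating truth."""
    key: str
    response: str
    coefficients: dict            # predictor -> unstandardized beta
    adj_r2: float
    intercept: float


#: the study's five regression models: RAU-transformed speech score on
#: SNR/masker type/group (a), individually rank-normalized effort (b),
#: RAU score on rank-normalized effort (c), z-scored log response time
#: (d) and z-scored response speech rate (e).  Intercepts are not
#: printed in the source table; values here center the predictions
#: (score ~50 RAU at SRT, effort/timing mid-scale) and recovery of the
#: slopes is intercept-invariant.
STUDY_MODELS = {
    "a": LatentLinearModel("a", "rau_score",
                           {"snr_re_srt": 3.813, "masker_type": 13.390, "group": -0.845},
                           adj_r2=0.719, intercept=31.1),
    "b": LatentLinearModel("b", "srle_rank_individual",
                           {"snr_re_srt": -0.174, "masker_type": -0.663, "group": 0.070},
                           adj_r2=0.813, intercept=1.94),
    "c": LatentLinearModel("c", "rau_score",
                           {"srle_rank_individual": -20.349, "masker_type": -0.094,
                            "group": 0.587},
                           adj_r2=0.782, intercept=49.3),
    "d": LatentLinearModel("d", "z_log_vrt",
                           {"snr_re_srt": -0.183, "masker_type": -0.679, "group": 0.000},
                           adj_r2=0.798, intercept=2.12),
    "e": LatentLinearModel("e", "z_rsr",
                           {"snr_re_srt": 0.157, "masker_type": 0.414, "group": 0.000},
                           adj_r2=0.538, intercept=-1.563),
}


def design_cells(n_nh: int = 15, n_hi: int = 12,
                 snr_offsets=DEFAULT_SNR_OFFSETS) -> pd.DataFrame:
    """The aggregate design: one row per listener x masker type x SNR."""
    rows = []
    for i in range(n_nh + n_hi):
        group = 1 if i < n_nh else 2
        for mtype in (FLUCTUATING, STATIONARY):
            for snr in snr_offsets:
                rows.append({"listener": i + 1, "group": group,
                             "masker_type": mtype, "snr_re_srt": float(snr)})
    return pd.DataFrame(rows)


def calibrate_residual_sd(linear_predictor, adj_r2: float) -> float:
    """Residual SD giving the target R²: sigma² = Var(lp)·(1-R²)/R²."""
    lp = np.asarray(linear_predictor, dtype=float)
    if not 0 < adj_r2 < 1:
        raise ValueError("R² must be in (0, 1)")
    return float(np.sqrt(lp.var(ddof=0) * (1.0 - adj_r2) / adj_r2))


def generate_latent_cells(model: LatentLinearModel | str, seed,
                          cells: pd.DataFrame | None = None,
                          residual_sd: float | None = None) -> pd.DataFrame:
    """Draw the per-cell response for one model with calibrated noise.

    For model (c), whose covariate is the rank-normalized effort rating,
    the covariate is itself generated from the model (b) truth first.
    Returns the cell table with the covariates and the response column.
    """
    if isinstance(model, str):
        model = STUDY_MODELS[model]
    cells = (cells if cells is not None else design_cells()).copy()
    rng = np.random.default_rng(seed)
    if "srle_rank_individual" in model.coefficients and \
            "srle_rank_individual" not in cells.columns:
        b = STUDY_MODELS["b"]
        lp_b = b.intercept + sum(v * cells[k] for k, v in b.coefficients.items())
        sd_b = calibrate_residual_sd(lp_b, b.adj_r2)
        cells["srle_rank_individual"] = lp_b + rng.normal(0.0, sd_b, len(cells))
    lp = model.intercept + sum(v * cells[k] for k, v in model.coefficients.items())
    sd = calibrate_residual_sd(lp, model.adj_r2) if residual_sd is None else residual_sd
    cells[model.response] = lp + rng.normal(0.0, sd, len(cells))
    return cells


def recover_model(model_key: str, seed, entry_p: float = 0.05,
                  removal_p: float = 0.10):
    """Generate one latent-linear cohort and refit the stepwise model.

    Returns the :class:`speechresp.stats.RegressionResult` of regressing
    the model's response on its candidate predictors for one seed.
    """
    from .stats import fit_stepwise
    model = STUDY_MODELS[model_key]
    cells = generate_latent_cells(model, seed=seed)
    return fit_stepwise(cells[model.response].to_numpy(),
                        cells[list(model.coefficients)],
                        entry_p=entry_p, removal_p=removal_p)


def recovery_experiment(model_key: str, n_seeds: int = 100,
                        master_seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo coefficient recovery for one regression model.

    Draws ``n_seeds`` independent synthetic cohorts (seeds derived from
    the master seed), refits the stepwise regression on each, and
    returns one row per seed with the recovered coefficient and an
    ``<name>_entered`` flag per candidate predictor.
    """
    model = STUDY_MODELS[model_key]
    key_index = sorted(STUDY_MODELS).index(model_key)
    seeds = np.random.SeedSequence([int(master_seed), key_index]).generate_state(n_seeds)
    rows = []
    for s in seeds:
        res = recover_model(model_key, int(s))
        row = {}
        for name in model.coefficients:
            row[name] = res.row(name).beta
            row[f"{name}_entered"] = res.row(name).entered
        rows.append(row)
    return pd.DataFrame(rows)
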