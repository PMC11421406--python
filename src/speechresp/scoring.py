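"""Word scoring, block scores, the unrecorded-block correction, RAU,
and aggregation to the per-cell analysis table.

Scoring is slot-wise: a response word counts as correct only if it is
the word presented in its own matrix slot (each of the five slots has a
disjoint word set, so a token identifies its slot unambiguously; each
response token is consumed at most once and ``<OOV>`` never matches).
Block scores are the percentage of the 25 presented words repeated
correctly.  Proportion-correct scores are variance-stabilized with
Studebaker's rationalized arcsine transform before linear modelling:

    theta = arcsin sqrt(x/(n+1)) + arcsin sqrt((x+1)/(n+1))
    RAU   = (146/pi) * theta - 23

computed here on pooled cell counts (x correct of n presented words in
the cell) rather than on averaged percentages, since the transform is
defined on counts; ``rau_on_counts=False`` selects the averaged-
percentage variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ResponseAlignment
from .vocabulary import OOV, Vocabulary, DEFAULT_VOCABULARY
from . import timing as _timing
from .normalize import rankit, zscore_within

WORDS_PER_SENTENCE = 5
SENTENCES_PER_BLOCK = 5


@dataclass
class ScoreRecord:
    trial_key: tuple
    n_correct: int
    n_presented: int = WORDS_PER_SENTENCE
    source: str = "ASR"

    def __post_init__(self):
        if not 0 <= self.n_correct <= self.n_presented:
            raise ValueError(f"n_correct {self.n_correct} outside 0..{self.n_presented}")


def score_sentence(presented, response: ResponseAlignment,
                   vocabulary: Vocabulary = DEFAULT_VOCABULARY,
                   source: str = "ASR") -> ScoreRecord:
    """Slot-wise word score of one response against the presented sentence."""
    if len(presented) != WORDS_PER_SENTENCE:
        raise ValueError("a matrix sentence has exactly 5 words")
    for i, word in enumerate(presented):
        if word not in vocabulary:
            raise ValueError(f"presented word {word!r} not in the matrix vocabulary")
        if vocabulary.slot_of(word) != i:
            raise ValueError(f"presented word {word!r} does not belong in slot {i}")
    available = [tok for tok, _, _ in response.tokens if tok != OOV]
    n_correct = 0
    for word in presented:
        if word in available:
            available.remove(word)  # each response token consumed at most once
            n_correct += 1
    return ScoreRecord(trial_key=response.trial_key, n_correct=n_correct, source=source)


def block_score(records) -> float:
    """Percent of the block's 25 presented words repeated correctly."""
    records = list(records)
    if len(records) != SENTENCES_PER_BLOCK:
        raise ValueError("a block score needs exactly 5 sentence records")
    total = sum(r.n_correct for r in records)
    n = sum(r.n_presented for r in records)
    return 100.0 * total / n


def impute_unrecorded(block_asr, block_manual):
    """Fill unrecorded sentences' scores from the block's manual scores.

    A sentence whose recording is missing (``n_correct is None`` in the
    ASR channel) is filled with the mean manual score of the block's
    recorded sentences.  Raises if the whole block is unrecorded.
    """
    block_asr = list(block_asr)
    block_manual = list(block_manual)
    recorded_manual = [m.n_correct for a, m in zip(block_asr, block_manual)
                       if a.n_correct is not None]
    out = []
    for a, m in zip(block_asr, block_manual):
        if a.n_correct is None:
            if not recorded_manual:
                raise ValueError(f"block of {a.trial_key}: entirely unrecorded, cannot impute")
            fill = float(np.mean(recorded_manual))
            out.append(ImputedScore(trial_key=a.trial_key, n_correct=fill))
        else:
            out.append(a)
    return out


@dataclass
class ImputedScore:
    """A score filled in for an unrecorded sentence (fractional words allowed)."""
    trial_key: tuple
    n_correct: float
    n_presented: int = WORDS_PER_SENTENCE
    source: str = "imputed"


def rau_transform(x: float, n: int) -> float:
    """Studebaker's rationalized arcsine units for x correct of n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside 0..{n}")
    theta = math.asin(math.sqrt(x / (n + 1))) + math.asin(math.sqrt((x + 1) / (n + 1)))
    return (146.0 / math.pi) * theta - 23.0


def aggregate(trials: pd.DataFrame, scores: pd.DataFrame, ratings: pd.DataFrame,
              timing: pd.DataFrame, rau_on_counts: bool = True) -> pd.DataFrame:
    """Collapse per-sentence data to one row per listener x masker type x SNR.

    Speech scores and rank-normalized effort are averaged within the
    masker types; raw effort, VRT and RSR take the median; z-transformed
    measures are averaged.  For the full study design this yields
    listeners x 2 masker types x 5 SNRs = 270 rows.

    ``scores`` columns: listener_id, block_id, sentence_index, n_correct
    (ASR channel, post-imputation).  ``ratings``: listener_id, block_id,
    srle.  ``timing``: output of :func:`speechresp.timing.timing_table`.
    """
    trials = trials.copy()
    cell_keys = ["listener_id", "masker_type", "snr_re_srt"]
    meta_cols = ["listener_id", "group", "masker_type", "snr_re_srt", "block_id"]
    block_info = trials[meta_cols].drop_duplicates(["listener_id", "block_id"])

    # ratings: block level; rank-normalize globally and per participant
    r = ratings.merge(block_info, on=["listener_id", "block_id"], validate="one_to_one")
    r["srle_rank_global"] = rankit(r["srle"].to_numpy())
    r["srle_rank_individual"] = rankit(r["srle"].to_numpy(), r["listener_id"].to_numpy())

    # timing: sentence level; z-transform within participant
    t = timing.merge(trials[["listener_id", "block_id", "sentence_index",
                             "masker_type", "snr_re_srt"]],
                     on=["listener_id", "block_id", "sentence_index"], validate="one_to_one")
    t["z_log_vrt"] = zscore_within(t["log_vrt"].to_numpy(), t["listener_id"].to_numpy())
    t["z_rsr"] = zscore_within(t["rsr_wps"].to_numpy(), t["listener_id"].to_numpy())

    s = scores.merge(trials[["listener_id", "block_id", "sentence_index",
                             "group", "masker_type", "snr_re_srt"]],
                     on=["listener_id", "block_id", "sentence_index"], validate="one_to_one")

    rows = []
    for (listener, mtype, snr), s_cell in s.groupby(cell_keys, sort=True):
        group = int(s_cell["group"].iloc[0])
        blocks = s_cell.groupby("block_id")["n_correct"].sum()
        n_per_block = s_cell.groupby("block_id")["n_correct"].size() * WORDS_PER_SENTENCE
        block_pcts = 100.0 * blocks / n_per_block
        x = float(s_cell["n_correct"].sum())
        n = int(len(s_cell) * WORDS_PER_SENTENCE)
        if rau_on_counts:
            rau = rau_transform(x, n)
        else:
            rau = float(np.mean([rau_transform(b, 25) for b in blocks]))
        r_cell = r[(r["listener_id"] == listener) & (r["masker_type"] == mtype)
                   & (r["snr_re_srt"] == snr)]
        t_cell = t[(t["listener_id"] == listener) & (t["masker_type"] == mtype)
                   & (t["snr_re_srt"] == snr)]
        if r_cell.empty or t_cell.empty:
            raise ValueError(f"empty analysis cell: {listener}/{mtype}/{snr}")
        rows.append({
            "listener_id": listener,
            "group": group,
            "masker_type": int(mtype),
            "snr_re_srt": float(snr),
            "mean_score_pct": float(block_pcts.mean()),
            "rau_score": rau,
            "srle_median_raw": float(r_cell["srle"].median()),
            "srle_mean_rank_individual": float(r_cell["srle_rank_individual"].mean()),
            "srle_mean_rank_global": float(r_cell["srle_rank_global"].mean()),
            "vrt_median_s": float(t_cell["vrt_s"].median()),
            "z_logvrt_mean": float(t_cell["z_log_vrt"].mean()),
            "rsr_median_wps": float(t_cell["rsr_wps"].median()),
            "z_rsr_mean": float(t_cell["z_rsr"].mean()),
        })
    return pd.DataFrame(rows)
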