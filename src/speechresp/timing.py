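"""Verbal response time (VRT) and response speech rate (RSR).

VRT is the time from the end of the presented sentence to the onset of
the listener's first response word (matrix word or ``<OOV>``); it may be
negative when the listener starts before the sentence ends, with a
physiological floor of -150 ms (roughly the mean word duration minus the
shortest plausible reaction time to a known word).  Because the raw VRT
distribution is strongly right-skewed, it is analyzed on the scale

    log-VRT = 10 * ln((VRT + 0.15 s) / 0.15 s)

which maps the admissible range (-0.15 s, inf) onto the real line and
is ~0-100 for typical responses.  RSR is the number of responded words
divided by the span from the first word's onset to the last word's end,
pauses included, in words per second.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .io import ResponseAlignment

logger = logging.getLogger(__name__)

#: the transform's reference point; VRT must stay above -VRT_FLOOR_S
VRT_FLOOR_S = 0.15
#: values below this are clamped (one 30-ms grid step inside the floor)
VRT_CLAMP_S = -0.149


class NoResponse(Exception):
    """The trial has no response tokens; VRT/RSR are undefined."""


def compute_vrt(alignment: ResponseAlignment, sentence_end_s: float | None = None) -> float:
    """VRT in seconds: first token onset minus sentence end.

    Values below -0.149 s are clamped there with a warning so the log
    transform stays finite.  Raises :class:`NoResponse` on an empty
    alignment.
    """
    if alignment.n_tokens == 0:
        raise NoResponse(f"no response tokens for trial {alignment.trial_key}")
    end = alignment.sentence_end_s if sentence_end_s is None else sentence_end_s
    if end is None:
        raise ValueError(f"trial {alignment.trial_key}: sentence_end_s unknown")
    vrt = alignment.first_onset_s - end
    if vrt < VRT_CLAMP_S:
        logger.warning("trial %s: VRT %.3f s below floor, clamped to %.3f s",
                       alignment.trial_key, vrt, VRT_CLAMP_S)
        vrt = VRT_CLAMP_S
    return vrt


def manual_convention(vrt_s: float) -> float:
    """The examiner's convention: negative VRTs are set to 0 ms."""
    return max(0.0, vrt_s)


def log_vrt(vrt_s: float) -> float:
    """10*ln((VRT + 0.15)/0.15); strictly increasing on (-0.15, inf)."""
    if vrt_s <= -VRT_FLOOR_S:
        raise ValueError(f"VRT {vrt_s} s is at or below the -{VRT_FLOOR_S} s floor")
    return 10.0 * math.log((vrt_s + VRT_FLOOR_S) / VRT_FLOOR_S)


def inverse_log_vrt(value: float) -> float:
    """Inverse of :func:`log_vrt`: VRT = 0.15*(exp(L/10) - 1) seconds."""
    return VRT_FLOOR_S * (math.exp(value / 10.0) - 1.0)


def compute_rsr(alignment: ResponseAlignment) -> float:
    """Words per second over the span first-onset .. last-end, pauses included."""
    if alignment.n_tokens == 0:
        raise NoResponse(f"no response tokens for trial {alignment.trial_key}")
    span = alignment.last_end_s - alignment.first_onset_s
    if span <= 0:
        raise ValueError(f"trial {alignment.trial_key}: non-positive response span {span}")
    return alignment.n_tokens / span


def timing_table(alignments, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial timing measures for every alignment with >= 1 token.

    Trials with an empty alignment (no response) are omitted; the study's
    design guarantees at least one usable response per analysis cell.
    """
    ends = trials.set_index(["listener_id", "block_id", "sentence_index"])["sentence_end_s"]
    rows = []
    for ali in alignments:
        if ali.n_tokens == 0:
            continue
        end = ali.sentence_end_s
        if end is None:
            end = float(ends.loc[ali.trial_key])
        vrt = compute_vrt(ali, sentence_end_s=end)
        rows.append({
            "listener_id": ali.trial_key[0],
            "block_id": ali.trial_key[1],
            "sentence_index": ali.trial_key[2],
            "vrt_s": vrt,
            "vrt_manual_convention_s": manual_convention(vrt),
            "log_vrt": log_vrt(vrt),
            "rsr_wps": compute_rsr(ali),
            "n_response_words": ali.n_tokens,
        })
    return pd.DataFrame(rows, columns=[
        "listener_id", "block_id", "sentence_index", "vrt_s",
        "vrt_manual_convention_s", "log_vrt", "rsr_wps", "n_response_words",
    ])
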