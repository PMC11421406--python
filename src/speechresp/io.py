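"""Reading and writing the pipeline's on-disk formats.

Alignment records travel as NIST CTM (one recognized token per line:
``utterance_id channel onset duration token [confidence]``); trial,
rating, timing and result tables travel as RFC-4180 CSV via pandas.
The utterance id encodes the trial key as ``listener__block__sentence``.
All times are seconds from the start of the response recording; the
verbal response time of a trial is computed downstream relative to the
``sentence_end_s`` carried in the trial table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .vocabulary import OOV, Vocabulary, DEFAULT_VOCABULARY

logger = logging.getLogger(__name__)

#: time resolution of the recognizer's output grid, seconds
TIME_RESOLUTION_S = 0.03

TRIAL_COLUMNS = [
    "listener_id", "group", "masker_id", "masker_type", "snr_re_srt",
    "block_id", "sentence_index", "sentence", "sentence_end_s",
]

RATING_COLUMNS = ["listener_id", "block_id", "srle"]


class CtmParseError(ValueError):
    """A malformed CTM line, reported with its line number."""


class SchemaError(ValueError):
    """A table is missing a required column or violates a key constraint."""


@dataclass
class ResponseAlignment:
    """One trial's response as timed word tokens.

    ``tokens`` is an onset-ordered list of ``(token, onset_s, duration_s)``
    with tokens drawn from the 50-word matrix vocabulary or ``<OOV>``.
    ``sentence_end_s`` is the end of the presented sentence on the same
    timeline (filled from the trial table when known).
    """

    trial_key: tuple  # (listener_id, block_id, sentence_index)
    tokens: list = field(default_factory=list)
    sentence_end_s: float | None = None

    def __post_init__(self):
        self.tokens = sorted(self.tokens, key=lambda t: t[1])
        for tok, onset, dur in self.tokens:
            if dur <= 0:
                raise ValueError(f"{self.trial_key}: non-positive duration for {tok!r}")
            if onset < 0:
                raise ValueError(f"{self.trial_key}: negative onset for {tok!r}")

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    @property
    def first_onset_s(self) -> float | None:
        return self.tokens[0][1] if self.tokens else None

    @property
    def last_end_s(self) -> float | None:
        if not self.tokens:
            return None
        return max(onset + dur for _, onset, dur in self.tokens)


def encode_utterance_id(trial_key: tuple) -> str:
    listener, block, sentence = trial_key
    return f"{listener}__{block}__{sentence}"


def decode_utterance_id(utt: str) -> tuple:
    parts = utt.split("__")
    if len(parts) != 3:
        raise CtmParseError(f"utterance id {utt!r} does not encode listener__block__sentence")
    listener, block, sentence = parts
    return listener, int(block), int(sentence)


def read_ctm(path, vocabulary: Vocabulary = DEFAULT_VOCABULARY) -> list[ResponseAlignment]:
    """Parse a CTM file into alignment records grouped by utterance.

    Tokens not in the vocabulary are stored as ``<OOV>`` with a logged
    warning.  Raises :class:`CtmParseError` with the line number on a
    malformed line, ``ValueError`` on a negative onset.
    """
    groups: dict[tuple, list] = {}
    order: list[tuple] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(";;"):
                continue
            fields = line.split()
            if len(fields) not in (5, 6):
                raise CtmParseError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(fields)}")
            utt, _channel, onset_s, dur_s, token = fields[:5]
            try:
                onset = float(onset_s)
                dur = float(dur_s)
            except ValueError as exc:
                raise CtmParseError(f"{path}:{lineno}: non-numeric time field") from exc
            if onset < 0:
                raise ValueError(f"{path}:{lineno}: negative onset {onset}")
            mapped = vocabulary.canonical(token)
            if mapped == OOV and token != OOV:
                logger.warning("%s:%d: token %r not in vocabulary, mapped to %s",
                               path, lineno, token, OOV)
            key = decode_utterance_id(utt)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append((mapped, onset, dur))
    return [ResponseAlignment(trial_key=key, tokens=groups[key]) for key in order]


def write_ctm(alignments, path) -> None:
    """Write alignment records as CTM, times fixed to the 30-ms grid precision."""
    with open(path, "w", encoding="utf-8") as fh:
        for ali in alignments:
            utt = encode_utterance_id(ali.trial_key)
            for token, onset, dur in ali.tokens:
                fh.write(f"{utt} 1 {onset:.2f} {dur:.2f} {token}\n")


def read_trials(path) -> pd.DataFrame:
    """Read a trial table, validating schema and trial-key uniqueness."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table missing column(s): {', '.join(missing)}")
    key = ["listener_id", "block_id", "sentence_index"]
    if df.duplicated(subset=key).any():
        raise SchemaError("duplicate trial keys in trial table")
    return df


def write_table(rows, path) -> None:
    """Write a DataFrame (or records) as RFC-4180 CSV without the index."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"ratings table missing column(s): {', '.join(missing)}")
    if df.duplicated(subset=["listener_id", "block_id"]).any():
        raise SchemaError("duplicate (listener_id, block_id) keys in ratings table")
    return df
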