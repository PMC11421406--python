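"""Rank-based inverse-normal (Rankit) and within-participant z transforms.

Categorical listening-effort ratings are not interval-scaled, so before
linear modelling they are rank-normalized with the Rankit plotting
position: a value of rank r among n maps to Phi^-1((r - 0.5)/n), ties
receiving mean ranks.  Applied globally (one ranking over everyone's
ratings) this preserves between-participant differences; applied per
participant it removes each participant's idiosyncratic use of the
rating scale while keeping the within-participant effects of SNR and
masker type.  Timing measures are instead z-scored within participant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def rankit(values, participant_keys=None) -> np.ndarray:
    """Rankit rank-normalization, globally or within participants.

    value of mean-rank r among n -> Phi^-1((r - 0.5)/n).  If
    ``participant_keys`` is given, ranking is done separately within
    each participant's values (scope = per_participant).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank-normalize an empty series")
    if participant_keys is None:
        ranks = stats.rankdata(values, method="average")
        return stats.norm.ppf((ranks - 0.5) / values.size)
    keys = np.asarray(participant_keys)
    out = np.empty_like(values)
    for key in pd.unique(keys):
        mask = keys == key
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"empty scope unit for participant {key!r}")
        ranks = stats.rankdata(values[mask], method="average")
        out[mask] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def zscore_within(values, participant_keys) -> np.ndarray:
    """Within-participant z-score: (v - mean)/SD per participant, sample SD."""
    values = np.asarray(values, dtype=float)
    keys = np.asarray(participant_keys)
    out = np.empty_like(values)
    for key in pd.unique(keys):
        mask = keys == key
        sub = values[mask]
        if sub.size < 2:
            raise ValueError(f"participant {key!r}: need >=2 values to z-score")
        sd = sub.std(ddof=1)
        if sd == 0:
            raise ValueError(f"participant {key!r}: zero within-participant SD")
        out[mask] = (sub - sub.mean()) / sd
    return out
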