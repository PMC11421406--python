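"""End-to-end orchestration: simulate -> score -> time -> normalize ->
aggregate -> fit models -> report.

The full default run mirrors the study: 6075 simulated sentences, the
published missingness structure, per-cell aggregation to 270 rows
(listener x masker type x SNR re SRT), the five stepwise regression
models (a) RAU score on SNR/type/group, (b) individually rank-
normalized effort, (c) RAU score on rank-normalized effort, (d/e)
z-scored log-VRT and RSR, agreement ICCs between the recognizer and
the examiner channels, and per-participant correlations between the
timing measures and self-reported effort.  A fixed master seed makes
the whole bundle reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as _cohort
from . import io as _io
from . import scoring as _scoring
from . import stats as _stats
from . import timing as _timing
from .cohort import Cohort, CohortConfig, MissingnessPlan
from .vocabulary import DEFAULT_VOCABULARY

logger = logging.getLogger(__name__)

MODEL_SPECS = {
    "a": ("rau_score", ["snr_re_srt", "masker_type", "group"]),
    "b": ("srle_mean_rank_individual", ["snr_re_srt", "masker_type", "group"]),
    "c": ("rau_score", ["srle_mean_rank_individual", "masker_type", "group"]),
    "d": ("z_logvrt_mean", ["snr_re_srt", "masker_type", "group"]),
    "e": ("z_rsr_mean", ["snr_re_srt", "masker_type", "group"]),
}


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    mode: str = "psychometric"
    models: tuple = ("a", "b", "c", "d", "e")
    out_dir: str | Path | None = None
    seed: int = 0
    apply_missingness: bool = True


@dataclass
class ResultsBundle:
    trials: pd.DataFrame
    scores: pd.DataFrame          # recognizer channel, post-imputation
    manual_scores: pd.DataFrame
    timing: pd.DataFrame
    aggregate: pd.DataFrame
    regressions: dict             # model key -> stats.RegressionResult
    icc_scores: _stats.ICCResult
    icc_vrt: _stats.ICCResult
    correlations: dict            # "vrt"/"rsr" -> (per-participant, summary)
    n_imputed: int
    manifest: dict


def score_asr_channel(cohort: Cohort) -> tuple[pd.DataFrame, int]:
    """Per-sentence recognizer word scores, with the unrecorded-block fix.

    Unrecorded sentences (no recognizer output at all) are filled with
    the mean manual score of the block's recorded sentences; empty
    responses score 0.  Returns the score table and the number of
    imputations performed.
    """
    ali = {a.trial_key: a for a in cohort.alignments}
    manual = cohort.manual_scores.set_index(
        ["listener_id", "block_id", "sentence_index"])["n_correct"]
    rows = []
    to_impute = []
    for _, t in cohort.trials.iterrows():
        key = (t["listener_id"], int(t["block_id"]), int(t["sentence_index"]))
        if not t["recorded"]:
            to_impute.append(key)
            rows.append({"listener_id": key[0], "block_id": key[1],
                         "sentence_index": key[2], "n_correct": np.nan})
            continue
        a = ali[key]
        rec = _scoring.score_sentence(t["sentence"].split(), a)
        rows.append({"listener_id": key[0], "block_id": key[1],
                     "sentence_index": key[2], "n_correct": float(rec.n_correct)})
    scores = pd.DataFrame(rows)
    n_imputed = 0
    for key in to_impute:
        listener, block, _ = key
        in_block = (scores["listener_id"] == listener) & (scores["block_id"] == block)
        recorded = scores[in_block & scores["n_correct"].notna()]
        fill = manual.loc[[(listener, block, s) for s in recorded["sentence_index"]]]
        fill = fill.dropna()
        if fill.empty:
            raise ValueError(f"block {listener}/{block}: entirely unrecorded, cannot impute")
        scores.loc[in_block & scores["n_correct"].isna(), "n_correct"] = float(fill.mean())
        n_imputed += 1
        logger.info("imputed unrecorded sentence %s from block mean %.2f", key, fill.mean())
    return scores, n_imputed


def _agreement_iccs(cohort: Cohort, scores: pd.DataFrame,
                    timing: pd.DataFrame):
    """Recognizer-vs-examiner ICCs over the 270 aggregate cells."""
    meta = cohort.trials[["listener_id", "block_id", "sentence_index",
                          "masker_type", "snr_re_srt"]]
    s = scores.merge(meta, on=["listener_id", "block_id", "sentence_index"])
    m = cohort.manual_scores.copy()
    m["n_correct"] = m["n_correct"].fillna(0.0)  # examiner's "no response" scores 0
    m = m.merge(meta, on=["listener_id", "block_id", "sentence_index"])
    keys = ["listener_id", "masker_type", "snr_re_srt"]
    asr_cell = s.groupby(keys)["n_correct"].mean()
    man_cell = m.groupby(keys)["n_correct"].mean()
    both = pd.concat([asr_cell, man_cell], axis=1, keys=["asr", "manual"]).dropna()
    icc_scores = _stats.icc_absolute_agreement(both["asr"], both["manual"])

    t = timing.merge(meta, on=["listener_id", "block_id", "sentence_index"])
    # the examiner reads the same response but clamps negative times to 0
    t = t.assign(vrt_manual=t["vrt_manual_convention_s"])
    # recognizer-only trials have no manual time
    manual_ok = cohort.trials.set_index(
        ["listener_id", "block_id", "sentence_index"])["manual_response"]
    mask = [bool(manual_ok.loc[(r.listener_id, r.block_id, r.sentence_index)])
            for r in t.itertuples()]
    tm = t[mask]
    vrt_asr = t.groupby(keys)["vrt_s"].median()
    vrt_man = tm.groupby(keys)["vrt_manual"].median()
    both_v = pd.concat([vrt_asr, vrt_man], axis=1).dropna()
    icc_vrt = _stats.icc_absolute_agreement(both_v.iloc[:, 0], both_v.iloc[:, 1])
    return icc_scores, icc_vrt


def run(config: PipelineConfig | None = None) -> ResultsBundle:
    """Run the whole analysis; optionally write the results bundle to disk."""
    cfg = config or PipelineConfig()
    cohort = _cohort.simulate_cohort(cfg.cohort, seed=cfg.seed, mode=cfg.mode)
    if cfg.apply_missingness:
        cohort = _cohort.inject_missingness(
            cohort, cfg.cohort.missingness,
            seed=np.random.SeedSequence((cfg.seed, 2)).generate_state(1)[0])

    scores, n_imputed = score_asr_channel(cohort)
    timing = _timing.timing_table(cohort.alignments, cohort.trials)
    aggregate = _scoring.aggregate(cohort.trials, scores, cohort.ratings, timing)

    regressions = {}
    for key in cfg.models:
        response, predictors = MODEL_SPECS[key]
        regressions[key] = _stats.fit_stepwise(
            aggregate[response].to_numpy(), aggregate[predictors])

    icc_scores, icc_vrt = _agreement_iccs(cohort, scores, timing)

    correlations = {
        "vrt": _stats.per_participant_pearson(
            aggregate["z_logvrt_mean"], aggregate["srle_mean_rank_individual"],
            aggregate["listener_id"]),
        "rsr": _stats.per_participant_pearson(
            aggregate["z_rsr_mean"], aggregate["srle_mean_rank_individual"],
            aggregate["listener_id"]),
    }

    manifest = {
        "seed": int(cfg.seed),
        "mode": cfg.mode,
        "n_trials": int(len(cohort.trials)),
        "n_complete": cohort.n_complete,
        "n_imputed": n_imputed,
        "config_hash": hashlib.sha256(
            json.dumps(str(cfg.cohort), sort_keys=True).encode()).hexdigest()[:16],
    }
    bundle = ResultsBundle(
        trials=cohort.trials, scores=scores, manual_scores=cohort.manual_scores,
        timing=timing, aggregate=aggregate, regressions=regressions,
        icc_scores=icc_scores, icc_vrt=icc_vrt, correlations=correlations,
        n_imputed=n_imputed, manifest=manifest)
    if cfg.out_dir is not None:
        write_bundle(bundle, cfg.out_dir, cohort)
    return bundle


def write_bundle(bundle: ResultsBundle, out_dir, cohort: Cohort | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_table(bundle.trials, out / "trials.csv")
    _io.write_table(bundle.scores, out / "scores_asr.csv")
    _io.write_table(bundle.manual_scores, out / "scores_manual.csv")
    _io.write_table(bundle.timing, out / "timing.csv")
    _io.write_table(bundle.aggregate, out / "aggregate.csv")
    if cohort is not None:
        _io.write_ctm(cohort.alignments, out / "alignments.ctm")
        _io.write_table(cohort.ratings, out / "ratings.csv")
    reg_rows = []
    for key, res in bundle.regressions.items():
        for p in res.predictors:
            reg_rows.append({"model": key, **vars(p), "adj_r2": res.adj_r2,
                             "durbin_watson": res.durbin_watson})
    _io.write_table(pd.DataFrame(reg_rows), out / "regressions.csv")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))
    (out / "report.md").write_text(report(bundle))


def report(bundle: ResultsBundle) -> str:
    """Human-readable summary of a results bundle (markdown)."""
    required = ["aggregate", "regressions", "icc_scores", "icc_vrt", "correlations"]
    missing = [name for name in required if getattr(bundle, name, None) is None
               or (hasattr(getattr(bundle, name), "__len__") and len(getattr(bundle, name)) == 0)]
    if missing:
        raise ValueError(f"incomplete results bundle; missing: {', '.join(missing)}")
    lines = ["# Speech-audiometry response analysis", ""]
    lines.append(f"Trials: {bundle.manifest['n_trials']}  "
                 f"(complete: {bundle.manifest['n_complete']}, "
                 f"imputed: {bundle.manifest['n_imputed']})")
    lines.append(f"Aggregate cells: {len(bundle.aggregate)}")
    lines.append("")
    lines.append("## Agreement between recognizer and examiner")
    lines.append(f"- speech-recognition scores: ICC(A,1) = {bundle.icc_scores.icc:.3f}")
    lines.append(f"- verbal response time:      ICC(A,1) = {bundle.icc_vrt.icc:.3f}")
    lines.append("")
    for key, res in bundle.regressions.items():
        response, _ = MODEL_SPECS[key]
        lines.append(f"## Model ({key}): {response}")
        lines.append(f"adjusted R² = {res.adj_r2:.3f}, "
                     f"Durbin–Watson d = {res.durbin_watson:.2f}, "
                     f"entered: {', '.join(res.entry_order)}")
        for p in res.predictors:
            flag = "" if p.entered else " (not entered)"
            lines.append(f"- {p.name}: beta = {p.beta:.3f} (SE {p.se:.3f}, "
                         f"std {p.std_beta:.3f}, CI [{p.ci_lower:.3f}, {p.ci_upper:.3f}], "
                         f"p = {p.p_change:.3g}){flag}")
        lines.append("")
    lines.append("## Per-participant correlations with self-reported effort")
    for name, label in (("vrt", "z(log VRT)"), ("rsr", "z(RSR)")):
        _, summary = bundle.correlations[name]
        lines.append(f"- {label}: r in [{summary['min_r']:.3f}, {summary['max_r']:.3f}], "
                     f"mean r = {summary['mean_r']:.3f}")
    lines.append("")
    return "\n".join(lines)
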