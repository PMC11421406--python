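"""Statistical machinery: ICC (two-way mixed, absolute agreement),
stepwise linear regression with diagnostics, per-participant
correlations, and thin wrappers over standard tests.

The ICC quantifies absolute agreement between two measurement channels
(e.g., a human examiner and an automatic recognizer scoring the same
trials): it is computed from the two-way (targets x raters) ANOVA mean
squares and, unlike a Pearson correlation, is penalized by systematic
offsets between the channels.

The stepwise regression mirrors the classical forward procedure with
default entry at p <= .05 and removal at p >= .10 of the coefficient's
F-to-enter/remove; candidates that never enter are still reported with
the coefficient they would have if added to the final model, so the
output has one row per candidate predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.stattools import durbin_watson as _sm_dw


# --------------------------------------------------------------------------
# intraclass correlation, ICC(A,1)

@dataclass
class ICCResult:
    icc: float
    model: str = "two-way mixed"
    type: str = "absolute agreement"
    unit: str = "single measures"
    n: int = 0


def icc_absolute_agreement(x, y) -> ICCResult:
    """ICC(A,1): single-measure absolute agreement of two paired series.

    Computed from the two-way layout's mean squares (rows = targets,
    columns = the two raters):

        ICC(A,1) = (MS_R - MS_E) / (MS_R + MS_E + (2/n)(MS_C - MS_E))
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance; ICC undefined")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))
    return ICCResult(icc=float(icc), n=n)


# --------------------------------------------------------------------------
# stepwise OLS with diagnostics

@dataclass
class PredictorRow:
    name: str
    beta: float
    se: float
    std_beta: float
    ci_lower: float
    ci_upper: float
    p_change: float
    entered: bool


@dataclass
class RegressionResult:
    predictors: list
    entry_order: list
    adj_r2: float
    r2: float
    f_stat: float
    df_model: int
    df_resid: int
    durbin_watson: float
    intercept: float

    def row(self, name: str) -> PredictorRow:
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.predictors])


def durbin_watson(residuals) -> float:
    """d = sum (e_t - e_{t-1})^2 / sum e_t^2, in [0, 4]; ~2 under no autocorrelation."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 residuals")
    if np.allclose(e, 0):
        raise ValueError("all-zero residuals; Durbin-Watson undefined")
    return float(_sm_dw(e))


def _fit_ols(y, X):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def fit_stepwise(y, candidates: pd.DataFrame, entry_p: float = 0.05,
                 removal_p: float = 0.10) -> RegressionResult:
    """Forward-stepwise OLS over an ordered candidate set.

    At each step the candidate with the smallest p-to-enter is added if
    p <= ``entry_p``; after each addition, included predictors with
    p >= ``removal_p`` are dropped.  All candidates are reported:
    non-entered ones with the coefficient they would take if added to
    the final model (flagged ``entered=False``).
    """
    y = np.asarray(y, dtype=float)
    names = list(candidates.columns)
    X = candidates.astype(float)
    for name in names:
        if np.isclose(X[name].std(ddof=0), 0):
            raise ValueError(f"candidate {name!r} is constant")
    included: list[str] = []
    while True:
        changed = False
        remaining = [n for n in names if n not in included]
        if remaining:
            pvals = {}
            for name in remaining:
                model = _fit_ols(y, X[included + [name]])
                pvals[name] = model.pvalues.get(name, np.nan)
            best = min(pvals, key=pvals.get)
            if pvals[best] <= entry_p:
                included.append(best)
                changed = True
        if included:
            model = _fit_ols(y, X[included])
            worst = max(included, key=lambda n: model.pvalues[n])
            if model.pvalues[worst] >= removal_p and len(included) > 1:
                included.remove(worst)
                changed = True
        if not changed:
            break
    if not included:
        raise ValueError("no candidate met the entry criterion")

    final = _fit_ols(y, X[included])
    sd_y = y.std(ddof=1)
    rows = []
    for name in names:
        if name in included:
            fit, label = final, name
        else:
            fit, label = _fit_ols(y, X[included + [name]]), name
        beta = fit.params[label]
        se = fit.bse[label]
        ci = fit.conf_int()
        rows.append(PredictorRow(
            name=name,
            beta=float(beta),
            se=float(se),
            std_beta=float(beta * X[name].std(ddof=1) / sd_y),
            ci_lower=float(ci.loc[label, 0]),
            ci_upper=float(ci.loc[label, 1]),
            p_change=float(fit.pvalues[label]),
            entered=name in included,
        ))
    resid = np.asarray(final.resid)
    dw = float(_sm_dw(resid)) if not np.allclose(resid, 0) else float("nan")
    return RegressionResult(
        predictors=rows,
        entry_order=list(included),
        adj_r2=float(final.rsquared_adj),
        r2=float(final.rsquared),
        f_stat=float(final.fvalue),
        df_model=int(final.df_model),
        df_resid=int(final.df_resid),
        durbin_watson=dw,
        intercept=float(final.params["const"]),
    )


def collinearity_check(predictors: pd.DataFrame, threshold: float = 0.7):
    """Pairwise Pearson |r| matrix with flags for pairs above threshold."""
    for name in predictors.columns:
        if np.isclose(predictors[name].std(ddof=0), 0):
            raise ValueError(f"predictor {name!r} is constant")
    corr = predictors.corr(method="pearson")
    flagged = [(a, b, float(corr.loc[a, b]))
               for i, a in enumerate(corr.columns)
               for b in corr.columns[i + 1:]
               if abs(corr.loc[a, b]) > threshold]
    return {"correlation": corr, "threshold": threshold, "flagged": flagged}


def per_participant_pearson(x, y, participant_keys):
    """Pearson r (and two-sided p) of x vs y within each participant.

    Returns (per-participant list, summary dict with min/mean/max r);
    participants with zero variance are flagged and excluded from the
    summary.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keys = np.asarray(participant_keys)
    results, flagged = [], []
    for key in pd.unique(keys):
        mask = keys == key
        if mask.sum() < 3:
            raise ValueError(f"participant {key!r}: need >=3 pairs")
        xs, ys = x[mask], y[mask]
        if xs.std(ddof=0) == 0 or ys.std(ddof=0) == 0:
            flagged.append(key)
            continue
        r, p = sps.pearsonr(xs, ys)
        results.append({"participant": key, "r": float(r), "p": float(p)})
    rs = [d["r"] for d in results]
    summary = {
        "min_r": min(rs) if rs else float("nan"),
        "mean_r": float(np.mean(rs)) if rs else float("nan"),
        "max_r": max(rs) if rs else float("nan"),
        "flagged": flagged,
    }
    return results, summary


# --------------------------------------------------------------------------
# thin wrappers over standard tests

def independent_t(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    t, p = sps.ttest_ind(a, b)
    return {"t": float(t), "p": float(p), "df": a.size + b.size - 2}


def paired_t(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2:
        raise ValueError("need n >= 2 pairs")
    t, p = sps.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "df": a.size - 1}


def repeated_measures_anova(data: pd.DataFrame, dv: str, within: str, subject: str):
    """One-way repeated-measures ANOVA (subject x condition two-way layout)."""
    wide = data.pivot(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("unbalanced repeated-measures layout")
    arr = wide.to_numpy()
    n, k = arr.shape
    grand = arr.mean()
    ss_cond = n * np.sum((arr.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((arr.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((arr - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    f = (ss_cond / df1) / (ss_err / df2)
    p = sps.f.sf(f, df1, df2)
    return {"F": float(f), "df1": df1, "df2": df2, "p": float(p)}


def shapiro_wilk(a):
    a = np.asarray(a, float)
    if a.size < 3:
        raise ValueError("need n >= 3")
    w, p = sps.shapiro(a)
    return {"W": float(w), "p": float(p)}


def bonferroni(p_values, m: int | None = None):
    p = np.asarray(p_values, float)
    m = p.size if m is None else m
    return np.minimum(p * m, 1.0)
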