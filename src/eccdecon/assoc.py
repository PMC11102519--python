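"""Association models, signature scoring, batch correction and survival.

Univariate and multivariate linear models on min-max-normalized responses
with Benjamini–Hochberg correction; a weighted log2(cpm+1) signature score
(stemness-style); linear batch-effect removal on log-scale expression; and
Kaplan–Meier / log-rank comparison of sample groups.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def univariate_assoc(attributes: pd.DataFrame, response: pd.Series) -> pd.DataFrame:
    """One simple linear regression per attribute column against the
    (min-max-normalized) response; slope t-test p-values, BH-corrected
    across attributes. Zero-variance attributes are skipped with a warning.
    """
    common = attributes.index.intersection(response.index)
    rows = []
    for name in attributes.columns:
        x = attributes.loc[common, name].astype(float)
        if x.nunique() < 2:
            log.warning("attribute %r has zero variance; skipped", name)
            continue
        fit = scipy.stats.linregress(x, response.loc[common].astype(float))
        rows.append({"term": name, "estimate": fit.slope,
                     "p_value": fit.pvalue, "n": len(common)})
    out = pd.DataFrame(rows, columns=["term", "estimate", "p_value", "n"])
    if len(out):
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def multivariate_assoc(
    attributes: pd.DataFrame,
    response: pd.Series,
    exclusions: list[str] | None = None,
) -> pd.DataFrame:
    """One joint OLS model of the response on all non-excluded attributes.

    Raises on a rank-deficient design (exact collinearity). The excluded
    terms are recorded in the result's ``attrs``.
    """
    exclusions = list(exclusions or [])
    kept = [c for c in attributes.columns if c not in exclusions]
    if not kept:
        raise ValueError("no attributes left after exclusions")
    common = attributes.index.intersection(response.index)
    X = attributes.loc[common, kept].astype(float)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design: exactly collinear attributes")
    fit = sm.OLS(response.loc[common].astype(float), design).fit()
    out = pd.DataFrame(
        {
            "term": kept,
            "estimate": [fit.params[c] for c in kept],
            "p_value": [fit.pvalues[c] for c in kept],
            "n": len(common),
        }
    )
    out.attrs["excluded"] = exclusions
    out.attrs["r_squared"] = float(fit.rsquared)
    return out


def signature_score(cpm: pd.DataFrame, weights: dict[str, float]) -> pd.Series:
    """Weighted gene signature on cpm-normalized expression:
    score_s = sum_g w_g * log2(cpm_gs + 1) over signature genes present.

    Missing signature genes are dropped with a warning; an empty overlap is
    an error.
    """
    present = [g for g in weights if g in cpm.index]
    missing = sorted(set(weights) - set(present))
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    if missing:
        log.warning("%d signature genes absent: %s", len(missing), missing[:5])
    w = np.array([weights[g] for g in present])
    logx = np.log2(cpm.loc[present].to_numpy(dtype=float) + 1.0)
    return pd.Series(w @ logx, index=cpm.columns, name="signature_score")


def batch_correct(log_expression: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
    """Remove additive batch effects per feature on log-scale expression.

    For each feature, the per-batch mean deviation from the feature's grand
    mean is subtracted from that batch's samples, so the per-feature grand
    mean is preserved and a purely additive batch shift vanishes exactly.
    A single batch is a warned no-op.
    """
    batch = batch.reindex(log_expression.columns)
    if batch.isna().any():
        raise ValueError("every sample needs a batch label")
    levels = batch.unique()
    if len(levels) < 2:
        log.warning("single batch: returning the matrix unchanged")
        return log_expression.copy()
    sizes = batch.value_counts()
    if (sizes < 2).any():
        raise ValueError("each batch needs at least 2 samples")
    X = log_expression.to_numpy(dtype=float)
    grand = X.mean(axis=1, keepdims=True)
    out = X.copy()
    for b in levels:
        cols = (batch == b).to_numpy()
        dev = X[:, cols].mean(axis=1, keepdims=True) - grand
        out[:, cols] -= dev
    return pd.DataFrame(out, index=log_expression.index,
                        columns=log_expression.columns)


def median_split(scores: pd.Series) -> pd.Series:
    """Binary low/high labels at the median: score > median -> 'high',
    score <= median -> 'low' (ties to 'low')."""
    if len(scores) < 2:
        raise ValueError("need at least 2 samples")
    if scores.nunique() < 2:
        raise ValueError("constant scores cannot be split")
    med = scores.median()
    return pd.Series(np.where(scores > med, "high", "low"),
                     index=scores.index, name="group")


def km_logrank(survival: pd.DataFrame) -> dict:
    """Kaplan–Meier curves per group and the multi-group log-rank test.

    ``survival`` needs time / event / group columns (event 1 = death).
    Returns the per-group product-limit step functions as a long-form
    DataFrame (group, time, survival), the log-rank chi-square statistic,
    its degrees of freedom (groups - 1) and two-sided p-value.
    """
    for col in ("time", "event", "group"):
        if col not in survival.columns:
            raise ValueError(f"survival table is missing column '{col}'")
    if (survival["time"] < 0).any():
        raise ValueError("negative survival times")
    if not set(survival["event"].unique()) <= {0, 1}:
        raise ValueError("event flags must be 0/1")
    groups = survival["group"].unique()
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if survival["event"].sum() < 1:
        raise ValueError("no events observed")

    curves = []
    for g in groups:
        sub = survival[survival["group"] == g]
        if len(sub) == 0:
            raise ValueError(f"group {g!r} has zero samples")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_.iloc[:, 0]
        curves.append(pd.DataFrame(
            {"group": g, "time": sf.index.to_numpy(), "survival": sf.to_numpy()}
        ))
    lr = multivariate_logrank_test(
        survival["time"], survival["group"], survival["event"]
    )
    return {
        "curves": pd.concat(curves, ignore_index=True),
        "chi2": float(lr.test_statistic),
        "df": len(groups) - 1,
        "p_value": float(lr.p_value),
    }
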