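"""Ex-vivo drug-resistance prediction and association from compositions.

Per drug, a random-forest regressor maps the per-sample cell-composition
vector to min-max-normalized AUC (higher = more resistant) under
leave-one-out cross-validation; performance is the Spearman correlation
between held-out predictions and observations. Univariate linear models
quantify per-(cell type, drug) associations with Benjamini–Hochberg FDR
across all pairs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def minmax_normalize(values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """(x - min) / (max - min); requires at least two distinct values."""
    arr = np.asarray(values, dtype=float)
    lo, hi = np.min(arr), np.max(arr)
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant vector")
    out = (arr - lo) / (hi - lo)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties and the two-sided
    t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    res = scipy.stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _fold_seed(seed: int, sample_id: str) -> int:
    """Deterministic per-fold seed from (global seed, sample id): LOOCV
    output is then invariant to sample ordering."""
    return zlib.crc32(f"{seed}|{sample_id}".encode()) & 0x7FFFFFFF


@dataclass
class DrugPredictionResult:
    drug: str
    predictions: pd.Series  # held-out prediction per sample
    observed: pd.Series
    spearman_rho: float
    spearman_p: float
    n_samples: int
    model_config: dict = field(default_factory=dict)


def loocv_predict(
    ecc: pd.DataFrame,
    response: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
    drug: str = "drug",
) -> DrugPredictionResult:
    """Leave-one-out random-forest prediction of normalized drug resistance.

    Features are the K composition columns; each sample is predicted by a
    forest trained on all other samples, with a fresh seed derived from the
    global seed and the held-out sample's id. Forest defaults mirror the
    conventional regression settings: ``n_trees`` trees, floor(K/3) (>= 1)
    features per split, unlimited depth.
    """
    # canonical (sorted) sample order: together with per-fold seeds this
    # makes the predictions invariant to input ordering
    common = ecc.index.intersection(response.index).sort_values()
    if len(common) < 10:
        raise ValueError(f"only {len(common)} matched samples (minimum 10)")
    if response.loc[common].nunique() < 2:
        raise ValueError("constant response")
    X = ecc.loc[common].to_numpy(dtype=float)
    y = response.loc[common].to_numpy(dtype=float)
    mtry = max(1, ecc.shape[1] // 3)

    preds = np.empty(len(common))
    for i, sid in enumerate(common):
        mask = np.ones(len(common), dtype=bool)
        mask[i] = False
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=mtry,
            random_state=_fold_seed(seed, str(sid)),
            n_jobs=1,
        )
        rf.fit(X[mask], y[mask])
        preds[i] = rf.predict(X[i : i + 1])[0]

    rho, p = spearman_rho(preds, y)
    return DrugPredictionResult(
        drug=drug,
        predictions=pd.Series(preds, index=common, name="predicted"),
        observed=pd.Series(y, index=common, name="observed"),
        spearman_rho=rho,
        spearman_p=p,
        n_samples=len(common),
        model_config={"n_trees": n_trees, "max_features": mtry, "seed": seed},
    )


def stratified_association(
    pred: DrugPredictionResult,
    class_labels: pd.Series,
    min_class_size: int = 4,
) -> pd.DataFrame:
    """Within each diagnosis class, linear regression of observed on
    predicted resistance: n, R^2 and slope p-value per class. Classes below
    ``min_class_size`` samples are skipped (logged)."""
    rows = []
    labels = class_labels.reindex(pred.predictions.index)
    for cls, idx in labels.groupby(labels).groups.items():
        if len(idx) < min_class_size:
            log.info("class %r skipped with %d < %d samples", cls, len(idx),
                     min_class_size)
            continue
        obs = pred.observed.loc[idx]
        pr = pred.predictions.loc[idx]
        if pr.nunique() < 2 or obs.nunique() < 2:
            log.info("class %r skipped: constant values", cls)
            continue
        fit = scipy.stats.linregress(pr, obs)
        rows.append(
            {"class": cls, "n": len(idx), "r_squared": fit.rvalue ** 2,
             "p_value": fit.pvalue}
        )
    return pd.DataFrame(rows, columns=["class", "n", "r_squared", "p_value"])


def ecc_drug_association(
    ecc: pd.DataFrame, drugs: pd.DataFrame
) -> pd.DataFrame:
    """Univariate association of normalized AUC with each composition column.

    ``drugs`` is long-form with sample_id / drug / auc (or auc_norm)
    columns; AUCs are min-max normalized per drug when not already. One
    linear regression per (cell type, drug) pair, Benjamini–Hochberg FDR
    across all pairs; the output carries the correlation for dot-plot
    sizing (size = |correlation|, sign = coefficient).
    """
    rows = []
    for drug, sub in drugs.groupby("drug"):
        sub = sub.set_index("sample_id")
        auc = (sub["auc_norm"] if "auc_norm" in sub.columns
               else minmax_normalize(sub["auc"]))
        common = ecc.index.intersection(auc.index)
        for ct in ecc.columns:
            x = ecc.loc[common, ct]
            if x.nunique() < 2:
                continue
            fit = scipy.stats.linregress(x, auc.loc[common])
            rows.append(
                {"cell_type": ct, "drug": drug, "coefficient": fit.slope,
                 "correlation": fit.rvalue, "p_value": fit.pvalue,
                 "n": len(common)}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
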