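"""Iteratively re-weighted non-negative least squares deconvolution.

Each bulk sample's relative expression is modelled as a non-negative
combination of per-type signature columns theta_k * cell_size_k. Per-gene
weights down-weight genes that are noisy across reference donors
(cross-subject variance, scaled by the current coefficients) or poorly fit
(squared residual), with a variance floor nu. Raw coefficients are divided
by cell size — converting mRNA-mass fractions into cell-count fractions —
and normalized to sum to one.

The solver works on non-log counts and performs no library normalization
beyond the conversion to relative expression (the "normalization off"
configuration); the relative bulk vector is scaled by 100 before fitting so
the default variance floor is on the engine's conventional scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .containers import BulkExpressionSet, ReferenceAtlas

log = logging.getLogger(__name__)


@dataclass
class DeconvolutionOptions:
    """Solver settings.

    nu
        variance floor added to every per-gene weight denominator.
    convergence_tol
        maximum absolute change of any proportion between successive
        weighted solves below which iteration stops.
    max_iter
        maximum number of weighted re-solves; 0 returns the initial
        unweighted NNLS solution (the unweighted limit).
    min_common_genes
        minimum bulk/atlas gene overlap required to attempt a fit.
    normalize
        kept for interface parity with the conventional engine; the
        pipeline runs with it off, as in the published configuration.
    """

    nu: float = 1e-4
    convergence_tol: float = 0.01
    max_iter: int = 1000
    min_common_genes: int = 100
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


@dataclass
class DeconvolutionResult:
    proportions: pd.DataFrame  # samples x cell types, rows sum to 1
    converged: pd.Series
    n_iter: pd.Series
    n_common_genes: int


def weighted_nnls(
    design: np.ndarray, response: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """argmin_{c >= 0} sum_g weights_g (response_g - design_g . c)^2.

    Exact active-set (Lawson–Hanson) solution via the square-root-weighted
    ordinary NNLS problem; deterministic.
    """
    design = np.asarray(design, dtype=float)
    response = np.asarray(response, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if design.ndim != 2 or design.shape[0] != response.shape[0]:
        raise ValueError("design and response dimensions disagree")
    if weights.shape != response.shape:
        raise ValueError("weights and response dimensions disagree")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(weights > 0):
        raise ValueError("all weights are zero")
    sw = np.sqrt(weights)
    coef, _ = scipy.optimize.nnls(design * sw[:, None], response * sw)
    return coef


def _fit_sample(
    y: np.ndarray,
    theta: np.ndarray,
    sigma2: np.ndarray,
    cell_size: np.ndarray,
    opts: DeconvolutionOptions,
) -> tuple[np.ndarray, bool, int]:
    """Iteratively re-weighted NNLS for one bulk sample.

    ``y`` is the shared-gene count vector; returns (proportions, converged,
    n_weighted_iterations).
    """
    total = y.sum()
    if total <= 0:
        raise ValueError("bulk sample has zero total counts on shared genes")
    # relative expression, scaled by 100 so nu sits on the engine scale
    yr = y / total * 100.0
    D = theta * cell_size[None, :]
    t = D.sum(axis=0)
    if np.any(t <= 0):
        raise ValueError("a cell type has no signature mass on shared genes")
    D = D / t

    def to_prop(x: np.ndarray) -> np.ndarray:
        p = x / cell_size
        s = p.sum()
        return p / s if s > 0 else np.full_like(p, 1.0 / len(p))

    x = weighted_nnls(D, yr, np.ones_like(yr))
    p = to_prop(x)
    if opts.max_iter == 0:
        return p, True, 0

    r = yr - D @ x
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        # cross-subject variance of the fitted value, on the theta*S scale
        c_eff = x * cell_size / t
        var_term = sigma2 @ (c_eff ** 2)
        w = 1.0 / (opts.nu + r ** 2 + var_term)
        x = weighted_nnls(D, yr, w)
        r = yr - D @ x
        p_new = to_prop(x)
        if np.max(np.abs(p_new - p)) < opts.convergence_tol:
            p = p_new
            converged = True
            break
        p = p_new
    return p, converged, it


def deconvolute(
    bulk: BulkExpressionSet | pd.DataFrame,
    atlas: ReferenceAtlas,
    opts: DeconvolutionOptions | None = None,
) -> DeconvolutionResult:
    """Estimate cell compositions for every bulk sample.

    Bulk counts must be non-log. Genes are intersected with the atlas
    (case-sensitive on identifiers) and each sample is fit independently;
    samples that do not converge within ``max_iter`` keep their last
    iterate and are flagged rather than dropped.
    """
    if opts is None:
        opts = DeconvolutionOptions()
    counts = bulk.counts if isinstance(bulk, BulkExpressionSet) else bulk

    atlas_idx = pd.Index(atlas.gene_ids)
    shared = counts.index.intersection(atlas_idx)
    log.info("deconvolute: %d shared genes (bulk %d, atlas %d)",
             len(shared), counts.shape[0], len(atlas_idx))
    if len(shared) < opts.min_common_genes:
        raise ValueError(
            f"only {len(shared)} genes shared between bulk and atlas "
            f"(minimum {opts.min_common_genes})"
        )
    pos = atlas_idx.get_indexer(shared)
    theta = atlas.theta[pos]
    sigma2 = atlas.sigma2[pos]
    Y = counts.loc[shared].to_numpy(dtype=float)

    props = np.zeros((counts.shape[1], atlas.n_types))
    converged = np.zeros(counts.shape[1], dtype=bool)
    n_iter = np.zeros(counts.shape[1], dtype=int)
    for i in range(counts.shape[1]):
        p, ok, it = _fit_sample(Y[:, i], theta, sigma2, atlas.cell_size, opts)
        props[i] = p
        converged[i] = ok
        n_iter[i] = it
        if not ok:
            log.warning("sample %s did not converge in %d iterations",
                        counts.columns[i], opts.max_iter)

    samples = pd.Index(counts.columns, name="sample_id")
    return DeconvolutionResult(
        proportions=pd.DataFrame(props, index=samples, columns=atlas.cell_types),
        converged=pd.Series(converged, index=samples),
        n_iter=pd.Series(n_iter, index=samples),
        n_common_genes=len(shared),
    )


def assign_phenotype(ecc: pd.DataFrame) -> pd.DataFrame:
    """Most-abundant-type phenotype per sample.

    Returns a frame with ``phenotype`` (argmax label; ties broken by atlas
    column order), ``dominance`` (the winning proportion) and ``tie``.
    """
    vals = ecc.to_numpy()
    best = vals.argmax(axis=1)
    dominance = vals[np.arange(len(vals)), best]
    tie = (vals == dominance[:, None]).sum(axis=1) > 1
    return pd.DataFrame(
        {
            "phenotype": [ecc.columns[j] for j in best],
            "dominance": dominance,
            "tie": tie,
        },
        index=ecc.index,
    )
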