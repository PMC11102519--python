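"""Synthetic data generators.

A multi-subject, multi-type negative-binomial single-cell atlas with
marker-gene structure, donor-level variability and library-size variation;
pseudobulk construction by the overabundant-type and per-individual schemes;
and downstream fixtures linking compositions to drug AUCs and survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AnnotatedCellMatrix

log = logging.getLogger(__name__)


@dataclass
class AtlasSimConfig:
    """Generative settings for the synthetic bone-marrow-like atlas.

    Defaults emulate a targeted panel of a few hundred genes profiled over a
    handful of healthy donors: 8 cell types x 3 subjects x 400 genes, 10
    dedicated marker genes per type up-regulated 2**3 = 8-fold, a moderate
    multiplicative donor effect (sd 0.25 on the natural-log scale),
    negative-binomial dispersion 0.25, and log-normal per-cell library sizes
    around 2000 counts.
    """

    n_types: int = 8
    n_subjects: int = 3
    n_genes: int = 400
    markers_per_type: int = 10
    marker_log2_foldchange: float = 3.0
    subject_sd: float = 0.25
    nb_dispersion: float = 0.25
    library_size_mean: float = 2000.0
    library_size_sd: float = 0.5
    cells_per_type_per_subject: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError("markers_per_type * n_types exceeds n_genes")
        for name in ("n_types", "n_subjects", "n_genes",
                     "cells_per_type_per_subject"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.nb_dispersion < 0 or self.subject_sd < 0:
            raise ValueError("dispersion and subject_sd must be non-negative")


@dataclass
class PseudobulkTruth:
    """A simulated bulk profile with its known composition."""

    bulk_counts: pd.Series
    true_proportions: pd.Series
    n_cells_drawn: pd.Series

    def __post_init__(self) -> None:
        if np.any(self.true_proportions < 0):
            raise ValueError("true_proportions must be non-negative")
        if not np.isclose(self.true_proportions.sum(), 1.0):
            raise ValueError("true_proportions must sum to 1")


def generate_synthetic_atlas(
    config: AtlasSimConfig | None = None, **overrides
) -> tuple[AnnotatedCellMatrix, dict]:
    """Draw a synthetic annotated single-cell count matrix.

    Per type k a baseline log-normal gene-mean profile is up-scaled
    ``2**marker_log2_foldchange`` on that type's dedicated marker genes;
    each subject applies an independent log-normal multiplicative effect per
    gene; each cell draws a log-normal library size and negative-binomial
    counts around the type/subject relative profile. Returns the cells and
    the generative parameters (marker assignment, type mean profiles,
    config) so tests can check recovery against ground truth. Fixed seed
    gives bit-identical output.
    """
    if config is None:
        config = AtlasSimConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    G, K, S = config.n_genes, config.n_types, config.n_subjects
    m, f = config.markers_per_type, config.marker_log2_foldchange

    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=G)
    marker_genes = {
        f"type{k}": np.arange(k * m, (k + 1) * m) for k in range(K)
    }
    type_means = np.tile(baseline, (K, 1)).T  # G x K
    for k in range(K):
        type_means[marker_genes[f"type{k}"], k] *= 2.0 ** f

    subject_effect = rng.lognormal(mean=0.0, sigma=config.subject_sd, size=(G, S))

    n_per = config.cells_per_type_per_subject
    n_cells = K * S * n_per
    counts = np.zeros((G, n_cells))
    cell_type = np.empty(n_cells, dtype=object)
    subject = np.empty(n_cells, dtype=object)
    disp = config.nb_dispersion
    mu_log = np.log(config.library_size_mean)

    col = 0
    for k in range(K):
        for s in range(S):
            rate = type_means[:, k] * subject_effect[:, s]
            rel = rate / rate.sum()
            lib = rng.lognormal(mean=mu_log, sigma=config.library_size_sd,
                                size=n_per)
            mu = rel[:, None] * lib[None, :]  # G x n_per expected counts
            if disp > 0:
                r = 1.0 / disp
                p = r / (r + mu)
                counts[:, col:col + n_per] = rng.negative_binomial(r, p)
            else:
                counts[:, col:col + n_per] = rng.poisson(mu)
            cell_type[col:col + n_per] = f"type{k}"
            subject[col:col + n_per] = f"subject{s}"
            col += n_per

    cells = AnnotatedCellMatrix(
        counts=counts,
        gene_ids=[f"gene{g}" for g in range(G)],
        cell_type=cell_type,
        subject=subject,
    )
    params = {
        "config": config,
        "marker_genes": marker_genes,
        "type_means": type_means,
        "subject_effect": subject_effect,
    }
    return cells, params


def allocate_inverse_proportion(available: pd.Series, total: int) -> pd.Series:
    """Integer allocation with weights inversely proportional to the number
    of available cells per type, largest-remainder rounding.

    Conserves ``total`` exactly for any positive weight vector.
    """
    w = 1.0 / available.astype(float)
    w = w / w.sum()
    raw = w * total
    base = np.floor(raw).astype(int)
    remainder = raw - base
    short = total - int(base.sum())
    # ties broken by position (stable sort) for determinism
    order = np.argsort(-remainder.to_numpy(), kind="stable")
    extra = np.zeros(len(available), dtype=int)
    extra[order[:short]] = 1
    return pd.Series(base.to_numpy() + extra, index=available.index)


def simulate_overabundant_pseudobulk(
    cells: AnnotatedCellMatrix,
    target_type: str,
    n_cells: int = 1000,
    frac: float = 0.8,
    seed: int | np.random.Generator = 0,
) -> PseudobulkTruth:
    """Overabundant-type pseudobulk: ``round(frac * n_cells)`` cells of the
    target type are drawn with replacement and the remaining cells are
    distributed over the other types with weights inversely proportional to
    their available cell counts, then all drawn cells' counts are summed.
    """
    cells = cells.delog()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    types = sorted(set(cells.cell_type))
    if target_type not in types:
        raise ValueError(f"target type {target_type!r} not present")
    if len(types) < 2:
        raise ValueError("need at least two cell types")

    n_target = int(round(frac * n_cells))
    others = [t for t in types if t != target_type]
    available = pd.Series(
        {t: int((cells.cell_type == t).sum()) for t in others}
    )
    n_other = allocate_inverse_proportion(available, n_cells - n_target)
    n_drawn = pd.Series(
        [n_target if t == target_type else int(n_other[t]) for t in types],
        index=pd.Index(types, name="cell_type"),
        dtype=int,
    )

    bulk = np.zeros(cells.n_genes)
    for t in types:
        n = int(n_drawn[t])
        if n == 0:
            continue
        pool = np.flatnonzero(cells.cell_type == t)
        picks = rng.choice(pool, size=n, replace=True)
        # multiplicity-weighted column sum
        idx, mult = np.unique(picks, return_counts=True)
        bulk += cells.counts[:, idx] @ mult

    return PseudobulkTruth(
        bulk_counts=pd.Series(bulk, index=pd.Index(cells.gene_ids, name="gene_id")),
        true_proportions=n_drawn / n_cells,
        n_cells_drawn=n_drawn,
    )


def aggregate_individual(cells: AnnotatedCellMatrix, subject: str) -> pd.Series:
    """Per-individual pseudobulk: the per-gene sum of one donor's cells."""
    cells = cells.delog()
    mask = cells.subject == subject
    if not mask.any():
        raise ValueError(f"unknown subject {subject!r}")
    return pd.Series(
        cells.counts[:, mask].sum(axis=1),
        index=pd.Index(cells.gene_ids, name="gene_id"),
    )


def generate_drug_response(
    ecc: pd.DataFrame,
    beta: np.ndarray | pd.Series,
    noise_sd: float,
    seed: int = 0,
    drug: str = "drug1",
) -> pd.DataFrame:
    """AUCs linearly linked to compositions: auc_i = beta . ecc_i + noise.

    ``ecc`` is samples x cell types; ``beta`` one coefficient per type. The
    generative beta is stored in the result's ``attrs``.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (ecc.shape[1],):
        raise ValueError("beta length must equal the number of cell types")
    rng = np.random.default_rng(seed)
    signal = ecc.to_numpy() @ beta
    auc = signal + rng.normal(0.0, noise_sd, size=len(signal))
    out = pd.DataFrame(
        {"sample_id": ecc.index, "drug": drug, "auc": auc}
    ).reset_index(drop=True)
    out.attrs["beta"] = beta
    out.attrs["seed"] = seed
    return out


def generate_survival(
    groups: pd.Series,
    hazard_by_group: dict[str, float],
    censor_time: float = np.inf,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times per group with administrative censoring.

    ``groups`` maps sample id -> group label; every label must have a
    positive hazard in ``hazard_by_group``. Records past ``censor_time``
    are censored (event=0) at ``censor_time``.
    """
    unknown = sorted(set(groups) - set(hazard_by_group))
    if unknown:
        raise ValueError(f"no hazard given for groups: {unknown[:5]}")
    if any(h <= 0 for h in hazard_by_group.values()):
        raise ValueError("hazards must be positive")
    rng = np.random.default_rng(seed)
    hazards = groups.map(hazard_by_group).to_numpy(dtype=float)
    raw = rng.exponential(1.0 / hazards)
    event = (raw <= censor_time).astype(int)
    time = np.minimum(raw, censor_time)
    return pd.DataFrame(
        {
            "sample_id": groups.index,
            "time": time,
            "event": event,
            "group": groups.to_numpy(),
        }
    ).reset_index(drop=True)
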