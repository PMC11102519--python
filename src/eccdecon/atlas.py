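"""Reference-atlas construction from an annotated single-cell matrix.

The deconvolution design needs, per cell type: the cross-subject mean
relative expression profile (theta), the cross-subject variance of the
subject-level relative profiles (sigma2), and the average library size of a
single cell (cell_size). Subject-level profiles — not pooled cells — define
theta, so donors contribute equally regardless of how many cells they
supplied; a pooled mode is available for comparison.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import AnnotatedCellMatrix, ReferenceAtlas

log = logging.getLogger(__name__)


def merge_celltype_labels(
    cells: AnnotatedCellMatrix,
    mapping: dict[str, str],
    strict: bool = False,
) -> AnnotatedCellMatrix:
    """Collapse fine cell-type labels via ``mapping`` (old -> new).

    Labels absent from the mapping pass through unchanged unless ``strict``
    is set, in which case they raise. Counts are untouched.
    """
    if strict:
        unmapped = sorted(set(cells.cell_type) - set(mapping))
        if unmapped:
            raise ValueError(f"unmapped cell-type labels: {unmapped[:5]}")
    new_labels = np.array([mapping.get(t, t) for t in cells.cell_type], dtype=object)
    return AnnotatedCellMatrix(
        counts=cells.counts,
        gene_ids=list(cells.gene_ids),
        cell_type=new_labels,
        subject=cells.subject.copy(),
        is_log_integrated=cells.is_log_integrated,
    )


def build_reference(
    cells: AnnotatedCellMatrix,
    min_cells_per_type: int = 10,
    pooled: bool = False,
) -> ReferenceAtlas:
    """Build the deconvolution design from annotated single cells.

    For each subject ``s`` and type ``k``, the subject-level profile is the
    average count vector over that subject's type-k cells, divided by its
    sum (relative expression). ``theta`` is the across-subject mean of
    these profiles and ``sigma2`` their across-subject variance (unbiased,
    ddof=1; zero when a single subject contributes). ``cell_size`` is the
    mean total count of a single type-k cell. Types with fewer than
    ``min_cells_per_type`` cells are dropped with a warning; genes with zero
    expression in every type are dropped (they carry no design
    information).

    With ``pooled=True`` theta is instead the relative mean profile over all
    pooled cells of the type; sigma2 is still the cross-subject variance.
    """
    cells = cells.delog()
    # sorted label order makes the atlas invariant to input cell order
    types = sorted(set(cells.cell_type))
    counts = cells.counts

    kept_types = []
    for t in types:
        n = int((cells.cell_type == t).sum())
        if n < min_cells_per_type:
            log.warning("dropping cell type %r with %d < %d cells", t, n,
                        min_cells_per_type)
        else:
            kept_types.append(t)
    if len(kept_types) < 2:
        raise ValueError("fewer than 2 cell types remain after filtering")

    subjects = sorted(set(cells.subject))
    G = cells.n_genes
    K = len(kept_types)
    theta = np.zeros((G, K))
    sigma2 = np.zeros((G, K))
    cell_size = np.zeros(K)
    n_cells = np.zeros(K, dtype=int)

    for j, t in enumerate(kept_types):
        type_mask = cells.cell_type == t
        sub_profiles = []
        for s in subjects:
            mask = type_mask & (cells.subject == s)
            if not mask.any():
                continue
            mean_expr = counts[:, mask].mean(axis=1)
            tot = mean_expr.sum()
            if tot <= 0:
                continue
            sub_profiles.append(mean_expr / tot)
        if not sub_profiles:
            raise ValueError(f"cell type {t!r} has zero total counts")
        P = np.column_stack(sub_profiles)
        theta[:, j] = P.mean(axis=1)
        sigma2[:, j] = P.var(axis=1, ddof=1) if P.shape[1] > 1 else 0.0
        if pooled:
            pooled_mean = counts[:, type_mask].mean(axis=1)
            theta[:, j] = pooled_mean / pooled_mean.sum()
        cell_size[j] = counts[:, type_mask].sum(axis=0).mean()
        n_cells[j] = int(type_mask.sum())

    expressed = theta.sum(axis=1) > 0
    n_zero = int((~expressed).sum())
    if n_zero:
        log.info("dropping %d genes with zero expression in all types", n_zero)
    theta = theta[expressed]
    sigma2 = sigma2[expressed]
    # renormalize after the zero-gene drop (no-op: dropped rows were zero)
    theta = theta / theta.sum(axis=0)

    return ReferenceAtlas(
        gene_ids=[g for g, e in zip(cells.gene_ids, expressed) if e],
        cell_types=kept_types,
        theta=theta,
        sigma2=sigma2,
        cell_size=cell_size,
        n_cells=n_cells,
        n_subjects=len(subjects),
    )


def write_atlas(atlas: ReferenceAtlas, path: str) -> None:
    """One structured TSV: comment header carries the per-type cell_size /
    n_cells and the subject count; the body holds theta and sigma2 blocks
    as ``theta:<type>`` / ``sigma2:<type>`` columns, one row per gene."""
    with open(path, "w") as fh:
        fh.write(f"# n_subjects\t{atlas.n_subjects}\n")
        for t, cs, nc in zip(atlas.cell_types, atlas.cell_size, atlas.n_cells):
            fh.write(f"# cell_type\t{t}\t{cs:.17g}\t{nc}\n")
        cols = {}
        for j, t in enumerate(atlas.cell_types):
            cols[f"theta:{t}"] = atlas.theta[:, j]
        for j, t in enumerate(atlas.cell_types):
            cols[f"sigma2:{t}"] = atlas.sigma2[:, j]
        df = pd.DataFrame(cols, index=pd.Index(atlas.gene_ids, name="gene_id"))
        df.to_csv(fh, sep="\t", float_format="%.17g")


def read_atlas(path: str) -> ReferenceAtlas:
    cell_types: list[str] = []
    cell_size: list[float] = []
    n_cells: list[int] = []
    n_subjects = 1
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            parts = line[1:].strip().split("\t")
            if parts[0] == "n_subjects":
                n_subjects = int(parts[1])
            elif parts[0] == "cell_type":
                cell_types.append(parts[1])
                cell_size.append(float(parts[2]))
                n_cells.append(int(parts[3]))
        df = pd.read_csv(fh, sep="\t", index_col=0)
    theta = df[[f"theta:{t}" for t in cell_types]].to_numpy()
    sigma2 = df[[f"sigma2:{t}" for t in cell_types]].to_numpy()
    return ReferenceAtlas(
        gene_ids=list(df.index),
        cell_types=cell_types,
        theta=theta,
        sigma2=sigma2,
        cell_size=np.array(cell_size),
        n_cells=np.array(n_cells, dtype=int),
        n_subjects=n_subjects,
    )
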