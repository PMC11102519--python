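"""Readers, writers and bulk preprocessing.

Bulk count matrices follow the conventional preprocessing for AML cohort
data: ERCC spike-ins and mitochondrial genes are removed, identifiers are
mapped to symbols with a user-supplied table, and among rows sharing a
symbol only the most variable row (largest per-gene standard deviation
across samples) is kept.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import AnnotatedCellMatrix, BulkExpressionSet

log = logging.getLogger(__name__)

#: floating-point format for all tabular output (6 significant digits)
FLOAT_FORMAT = "%.6g"


def gene_metadata(
    gene_ids: list[str],
    symbol_map: dict[str, str] | None = None,
    is_spikein: dict[str, bool] | None = None,
    is_mitochondrial: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Per-gene annotation table: spike-in / mitochondrial flags and symbol.

    Explicit flags take precedence when supplied; otherwise genes are
    recognised by the conventional prefixes ``ERCC-`` (spike-ins) and
    ``MT-`` (mitochondrial), case-insensitively. ``symbol_map`` maps ids to
    symbols; unmapped ids keep their own id as symbol. A map sending one id
    to two symbols is impossible by construction (dict), but a map given as
    a DataFrame-ish iterable of pairs is validated by the caller.
    """
    ids = pd.Index(gene_ids)
    if ids.duplicated().any():
        log.warning("gene_metadata: %d duplicated gene ids", ids.duplicated().sum())
    upper = ids.str.upper()
    spike = upper.str.startswith("ERCC-")
    mito = upper.str.startswith("MT-")
    meta = pd.DataFrame(
        {
            "is_spikein": spike,
            "is_mitochondrial": mito,
            "symbol": [
                (symbol_map or {}).get(g, g) for g in gene_ids
            ],
        },
        index=ids,
    )
    if is_spikein:
        for g, v in is_spikein.items():
            if g in meta.index:
                meta.loc[g, "is_spikein"] = bool(v)
    if is_mitochondrial:
        for g, v in is_mitochondrial.items():
            if g in meta.index:
                meta.loc[g, "is_mitochondrial"] = bool(v)
    return meta


def load_symbol_map(path: str) -> dict[str, str]:
    """Two-column TSV/CSV (gene_id, symbol) -> dict; conflicting duplicate
    mappings (one id, two symbols) are an error."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("mapping table needs two columns: gene_id, symbol")
    df = df.iloc[:, :2].drop_duplicates()
    dup = df.iloc[:, 0].duplicated(keep=False)
    if dup.any():
        bad = sorted(df.loc[dup, df.columns[0]].unique())
        raise ValueError(f"conflicting symbol mapping for: {bad[:5]}")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_cell_matrix(
    mtx_path: str,
    features_path: str,
    barcodes_path: str,
    annotation_path: str,
    cell_type_col: str = "cell_type",
    subject_col: str = "subject",
) -> AnnotatedCellMatrix:
    """Read a MatrixMarket triplet plus a per-barcode annotation table.

    The MTX file stores genes x cells counts; ``features_path`` and
    ``barcodes_path`` are one-column (or first-column) TSVs naming the rows
    and columns. The annotation TSV must carry one row per barcode with at
    least ``cell_type`` and ``subject`` columns; barcodes absent from the
    annotation are dropped (count logged).
    """
    mat = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    features = pd.read_csv(features_path, sep="\t", header=None).iloc[:, 0].astype(str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str)
    if len(features) != mat.shape[0]:
        raise ValueError(
            f"MTX has {mat.shape[0]} rows but features file has {len(features)}"
        )
    if len(barcodes) != mat.shape[1]:
        raise ValueError(
            f"MTX has {mat.shape[1]} columns but barcodes file has {len(barcodes)}"
        )
    ann = pd.read_csv(annotation_path, sep="\t", header=0, dtype=str)
    barcode_col = ann.columns[0]
    for col in (cell_type_col, subject_col):
        if col not in ann.columns:
            raise ValueError(f"annotation is missing required column '{col}'")
    ann = ann.set_index(barcode_col)
    keep = barcodes.isin(ann.index).to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        log.warning("dropping %d barcodes without annotation", n_drop)
    kept = barcodes[keep]
    ann = ann.loc[kept]
    return AnnotatedCellMatrix(
        counts=mat[:, keep],
        gene_ids=list(features),
        cell_type=ann[cell_type_col].to_numpy(),
        subject=ann[subject_col].to_numpy(),
    )


def write_cell_matrix(cells: AnnotatedCellMatrix, prefix: str) -> None:
    """Write MTX + features + barcodes + annotation under ``prefix``."""
    scipy.io.mmwrite(f"{prefix}.mtx", scipy.sparse.coo_matrix(cells.counts))
    pd.Series(cells.gene_ids).to_csv(f"{prefix}.features.tsv", sep="\t",
                                     header=False, index=False)
    barcodes = [f"cell{i}" for i in range(cells.n_cells)]
    pd.Series(barcodes).to_csv(f"{prefix}.barcodes.tsv", sep="\t",
                               header=False, index=False)
    pd.DataFrame(
        {"barcode": barcodes, "cell_type": cells.cell_type, "subject": cells.subject}
    ).to_csv(f"{prefix}.annotation.tsv", sep="\t", index=False)


def read_bulk_counts(tsv_path: str, meta_path: str | None = None) -> BulkExpressionSet:
    """Load a genes x samples TSV (first column = gene id) and optional
    per-sample metadata keyed on sample id."""
    counts = pd.read_csv(tsv_path, sep="\t", header=0, index_col=0)
    try:
        counts = counts.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric count value: {exc}") from exc
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative count values")
    meta = None
    if meta_path is not None:
        sep = "," if str(meta_path).endswith(".csv") else "\t"
        meta = pd.read_csv(meta_path, sep=sep, header=0, index_col=0)
        extra = meta.index.difference(counts.columns)
        if len(extra):
            log.warning("%d metadata rows without a matching sample ignored", len(extra))
            meta = meta.loc[meta.index.intersection(counts.columns)]
        meta = meta.reindex(counts.columns)
    return BulkExpressionSet(counts=counts, sample_meta=meta)


def preprocess_bulk(
    bulk: BulkExpressionSet,
    meta: pd.DataFrame | None = None,
    sd_ddof: int = 0,
) -> BulkExpressionSet:
    """Remove spike-ins and mitochondrial genes, map ids to symbols, and
    deduplicate symbols keeping the row with the largest standard deviation.

    The SD is computed on raw counts across samples (population SD,
    ``sd_ddof=0`` by default; configurable). Idempotent.
    """
    if meta is None:
        meta = gene_metadata(bulk.gene_ids)
    meta = meta.reindex(bulk.counts.index)
    drop = meta["is_spikein"].fillna(False) | meta["is_mitochondrial"].fillna(False)
    counts = bulk.counts.loc[~drop.to_numpy()]
    symbols = meta.loc[~drop.to_numpy(), "symbol"].fillna(
        pd.Series(counts.index, index=counts.index)
    )
    if counts.empty:
        raise ValueError("no genes left after spike-in/mitochondrial filtering")
    sd = counts.std(axis=1, ddof=sd_ddof)
    # keep, per symbol, the most variable row; ties resolved by first occurrence
    order = np.argsort(-sd.to_numpy(), kind="stable")
    seen: set[str] = set()
    keep_pos: list[int] = []
    for pos in order:
        sym = symbols.iloc[pos]
        if sym not in seen:
            seen.add(sym)
            keep_pos.append(pos)
    keep_pos.sort()
    out = counts.iloc[keep_pos].copy()
    out.index = symbols.iloc[keep_pos]
    out.index.name = bulk.counts.index.name
    n_dup = counts.shape[0] - out.shape[0]
    if n_dup:
        log.info("preprocess_bulk: removed %d duplicate-symbol rows", n_dup)
    return BulkExpressionSet(counts=out, sample_meta=bulk.sample_meta)


def cpm_normalize(bulk: BulkExpressionSet | pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: each column scaled to sum to 1e6."""
    counts = bulk.counts if isinstance(bulk, BulkExpressionSet) else bulk
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise ValueError(f"zero library size for samples: {bad[:5]}")
    return counts / libsize * 1e6


def write_table(df: pd.DataFrame, path: str, index: bool = True) -> None:
    """TSV with a header row; floats at 6 significant digits."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def write_ecc(result, path: str) -> None:
    """Serialize a deconvolution result: one row per sample with the per-type
    proportions, assigned phenotype, dominance, convergence flag and
    iteration count."""
    from .deconvolve import assign_phenotype

    df = result.proportions.copy()
    pheno = assign_phenotype(result.proportions)
    df["phenotype"] = pheno["phenotype"]
    df["dominance"] = pheno["dominance"]
    df["converged"] = result.converged
    df["n_iter"] = result.n_iter
    df.index.name = "sample_id"
    write_table(df, path)


def read_ecc(path: str) -> pd.DataFrame:
    """Read back the proportions block of an ECC table written by
    :func:`write_ecc` (annotation columns dropped)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.drop(columns=["phenotype", "dominance", "converged", "n_iter"],
                   errors="ignore")
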