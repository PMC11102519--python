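"""Core in-memory containers shared across the pipeline.

All matrices are gene-major (genes x cells / genes x samples), matching the
orientation of the deconvolution design; conversion helpers to the cell-major
AnnData convention are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class AnnotatedCellMatrix:
    """Single-cell counts with per-cell type and donor labels.

    Parameters
    ----------
    counts
        genes x cells matrix of non-negative expression values, non-log
        scale unless ``is_log_integrated`` is set (in which case values are
        natural-log1p integrated expression that must be exponentiated with
        ``expm1`` before any counting operation).
    gene_ids
        one identifier per row of ``counts``.
    cell_type
        one cell-type label per column.
    subject
        one donor label per column.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_type: np.ndarray
    subject: np.ndarray
    is_log_integrated: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        self.subject = np.asarray(self.subject, dtype=object)
        g, c = self.counts.shape
        if len(self.gene_ids) != g:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {g} count rows"
            )
        if len(self.cell_type) != c or len(self.subject) != c:
            raise ValueError("one cell_type and subject label required per cell")
        if not self.is_log_integrated and np.any(self.counts < 0):
            raise ValueError("negative values in a non-log count matrix")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_types(self) -> list[str]:
        """Distinct type labels in order of first appearance."""
        return list(pd.unique(self.cell_type))

    @property
    def subjects(self) -> list[str]:
        return list(pd.unique(self.subject))

    def delog(self) -> "AnnotatedCellMatrix":
        """Return a non-log copy, exponentiating (expm1) if flagged."""
        if not self.is_log_integrated:
            return self
        return AnnotatedCellMatrix(
            counts=np.expm1(self.counts),
            gene_ids=list(self.gene_ids),
            cell_type=self.cell_type.copy(),
            subject=self.subject.copy(),
            is_log_integrated=False,
        )

    def to_anndata(self):
        """Cell-major AnnData view (cells x genes) for interoperability."""
        import anndata as ad

        obs = pd.DataFrame(
            {"cell_type": self.cell_type, "subject": self.subject},
            index=[f"cell{i}" for i in range(self.n_cells)],
        )
        var = pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id"))
        return ad.AnnData(X=self.counts.T.copy(), obs=obs, var=var)

    @classmethod
    def from_anndata(cls, adata, cell_type_key: str = "cell_type",
                     subject_key: str = "subject") -> "AnnotatedCellMatrix":
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        return cls(
            counts=np.asarray(X).T,
            gene_ids=list(adata.var_names),
            cell_type=adata.obs[cell_type_key].to_numpy(),
            subject=adata.obs[subject_key].to_numpy(),
        )


@dataclass
class BulkExpressionSet:
    """Bulk RNA-seq counts (genes x samples) with optional sample metadata."""

    counts: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            # duplicates are legal pre-processing input; resolved by
            # preprocess_bulk, but sample ids must always be unique
            pass
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicated sample identifiers")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class ReferenceAtlas:
    """Per-(gene, cell type) design quantities for weighted deconvolution.

    ``theta`` holds cross-subject mean relative expression (columns sum to
    one), ``sigma2`` the cross-subject variance of the subject-level relative
    profiles, and ``cell_size`` the average library size (total counts) of a
    single cell of each type.
    """

    gene_ids: list[str]
    cell_types: list[str]
    theta: np.ndarray
    sigma2: np.ndarray
    cell_size: np.ndarray
    n_cells: np.ndarray
    n_subjects: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        self.cell_size = np.asarray(self.cell_size, dtype=float)
        self.n_cells = np.asarray(self.n_cells, dtype=int)
        G, K = self.theta.shape
        if len(self.gene_ids) != G or len(self.cell_types) != K:
            raise ValueError("theta shape inconsistent with labels")
        if self.sigma2.shape != (G, K):
            raise ValueError("sigma2 shape mismatch")
        if np.any(self.theta < -1e-12):
            raise ValueError("theta must be non-negative")
        colsums = self.theta.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-8):
            raise ValueError("theta columns must sum to 1")
        if np.any(self.sigma2 < 0):
            raise ValueError("sigma2 must be non-negative")
        if np.any(self.cell_size <= 0):
            raise ValueError("cell_size must be positive for retained types")

    @property
    def n_types(self) -> int:
        return len(self.cell_types)

    def subset_genes(self, genes: list[str], renormalize: bool = True) -> "ReferenceAtlas":
        """Restrict to ``genes`` (atlas order preserved), optionally
        renormalizing theta columns to sum to one."""
        idx = pd.Index(self.gene_ids)
        keep = idx.get_indexer([g for g in genes if g in idx])
        keep = keep[keep >= 0]
        theta = self.theta[keep]
        if renormalize:
            s = theta.sum(axis=0)
            if np.any(s <= 0):
                raise ValueError("a cell type has zero theta mass on the gene subset")
            theta = theta / s
        return ReferenceAtlas(
            gene_ids=[self.gene_ids[i] for i in keep],
            cell_types=list(self.cell_types),
            theta=theta,
            sigma2=self.sigma2[keep],
            cell_size=self.cell_size.copy(),
            n_cells=self.n_cells.copy(),
            n_subjects=self.n_subjects,
            extra=dict(self.extra),
        )
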