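"""In-memory containers for the expression pipeline.

Matrices are stored genes x cells (the orientation of a 10x MatrixMarket file)
as ``scipy.sparse`` matrices. Each container carries the replicate id and the
timepoint (day) it came from, so downstream comparisons can be organised
within and between timepoints without external bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

MITO_PREFIX = "mt-"


def _as_str_array(values) -> np.ndarray:
    return np.asarray(list(values), dtype=object)


@dataclass
class CountMatrix:
    """Raw UMI counts, genes x cells, with replicate/timepoint metadata.

    Parameters
    ----------
    counts
        Sparse integer matrix, genes as rows.
    gene_names, barcodes
        Row and column labels. Barcodes must be unique within a replicate.
    replicate
        Replicate identifier, e.g. ``"r1"``.
    day
        Timepoint in days post injury (0, 3, 7 or 21 in the study design).
    """

    counts: sp.spmatrix
    gene_names: np.ndarray
    barcodes: np.ndarray
    replicate: str = "r1"
    day: int = 0

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        if np.issubdtype(self.counts.dtype, np.floating):
            data = self.counts.data
            if data.size and not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        self.gene_names = _as_str_array(self.gene_names)
        self.barcodes = _as_str_array(self.barcodes)
        if self.counts.shape != (len(self.gene_names), len(self.barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_names)} genes x {len(self.barcodes)} cells"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes within a replicate")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_id(self) -> str:
        """Unique (day, replicate) label, e.g. ``"d7-r2"``."""
        return f"d{self.day}-{self.replicate}"

    @property
    def mito_mask(self) -> np.ndarray:
        """Boolean mask over genes marking mitochondrial genes by name prefix."""
        return np.array([g.startswith(MITO_PREFIX) for g in self.gene_names], dtype=bool)

    def genes_per_cell(self) -> np.ndarray:
        """Number of detected genes (count > 0) per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def umis_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Fraction of each cell's UMIs coming from mitochondrial genes."""
        total = self.umis_per_cell().astype(float)
        mito = np.asarray(self.counts[self.mito_mask, :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
        return frac

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        return CountMatrix(
            self.counts[gm][:, cm],
            self.gene_names[gm],
            self.barcodes[cm],
            replicate=self.replicate,
            day=self.day,
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells x genes) for interop."""
        import anndata as ad
        import pandas as pd

        adata = ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=pd.DataFrame(
                {"replicate": self.replicate, "day": self.day},
                index=list(self.barcodes),
            ),
            var=pd.DataFrame({"mito": self.mito_mask}, index=list(self.gene_names)),
        )
        return adata


@dataclass
class NormalizedMatrix:
    """Log-normalised expression: ``ln(1 + scale_factor * count / cell_total)``.

    Zeros stay zero, so the matrix remains sparse; the per-cell sum of
    ``expm1(values)`` recovers ``scale_factor`` exactly.
    """

    values: sp.spmatrix
    gene_names: np.ndarray
    barcodes: np.ndarray
    scale_factor: float = 1e4
    replicate: str = "r1"
    day: int = 0

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        self.gene_names = _as_str_array(self.gene_names)
        self.barcodes = _as_str_array(self.barcodes)
        if self.values.shape != (len(self.gene_names), len(self.barcodes)):
            raise ValueError("values shape inconsistent with labels")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("log-normalised values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def sample_id(self) -> str:
        return f"d{self.day}-{self.replicate}"

    def subset_genes(self, genes) -> "NormalizedMatrix":
        """Restrict to `genes`, in the given order. All must be present."""
        index = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        rows = np.array([index[g] for g in genes])
        return NormalizedMatrix(
            self.values[rows, :],
            np.asarray(list(genes), dtype=object),
            self.barcodes,
            scale_factor=self.scale_factor,
            replicate=self.replicate,
            day=self.day,
        )


@dataclass
class Embedding:
    """PCA embedding of cells.

    ``coordinates`` is cells x components; ``explained_variance`` is
    non-increasing; ``hvg`` records the highly variable genes the embedding
    was computed on.
    """

    coordinates: np.ndarray
    explained_variance: np.ndarray
    hvg: np.ndarray
    barcodes: np.ndarray
    loadings: np.ndarray = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if np.any(np.diff(self.explained_variance) > 1e-8 * max(1.0, self.explained_variance[0] if len(self.explained_variance) else 1.0)):
            raise ValueError("explained variances must be non-increasing")

    @property
    def n_cells(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class MergedMatrix:
    """Pooled log-normalised cells from several samples, with batch correction.

    ``values`` are the pooled uncorrected log-normalised values (genes x cells);
    ``corrected`` stores the batch-mean-centred values used for the final
    clustering. ``batches`` labels each cell with its source sample, ``days``
    and ``replicates`` unpack that label.
    """

    values: sp.spmatrix
    corrected: np.ndarray
    gene_names: np.ndarray
    barcodes: np.ndarray
    batches: np.ndarray
    days: np.ndarray
    replicates: np.ndarray
    scale_factor: float = 1e4

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        self.corrected = np.asarray(self.corrected, dtype=np.float64)
        self.gene_names = _as_str_array(self.gene_names)
        self.barcodes = _as_str_array(self.barcodes)
        self.batches = _as_str_array(self.batches)
        n_genes, n_cells = self.values.shape
        if self.corrected.shape != (n_genes, n_cells):
            raise ValueError("corrected values shape mismatch")
        for name, arr in [("barcodes", self.barcodes), ("batches", self.batches)]:
            if len(arr) != n_cells:
                raise ValueError(f"{name} length != cell count")
        self.days = np.asarray(self.days)
        self.replicates = _as_str_array(self.replicates)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]
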