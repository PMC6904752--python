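"""Quality control, log-normalisation, variable-gene selection and PCA.

Cell filters follow the study's thresholds literally: a cell is removed if it
detects *fewer than* 500 genes, has *more than* 10% of its UMIs on
mitochondrial genes, or *more than* 60 000 total UMIs — strict inequalities
trigger removal, equality retains. Genes expressed in fewer than 10 of the
surviving cells are then removed. Because removing genes can push cells below
the gene threshold again, the two filters are iterated to a fixed point, which
also makes the result independent of filter order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, NormalizedMatrix, Embedding


@dataclass
class QCParams:
    """Cell/gene filter thresholds (defaults are the study's)."""

    min_genes_per_cell: int = 500
    max_mito_fraction: float = 0.10
    max_umis_per_cell: int = 60_000
    min_cells_per_gene: int = 10

    def __post_init__(self):
        if min(self.min_genes_per_cell, self.max_umis_per_cell, self.min_cells_per_gene) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


@dataclass
class QCReport:
    """What QC removed and why."""

    removed_cells: pd.DataFrame  # barcode, reason
    removed_genes: list
    n_iterations: int = 1

    @property
    def n_cells_removed(self) -> int:
        return len(self.removed_cells)


class EmptyAfterQCError(ValueError):
    pass


def apply_qc(matrix: CountMatrix, params: QCParams = None):
    """Filter cells then genes, iterating to the fixed point.

    Returns ``(filtered_matrix, QCReport)``. Raises
    :class:`EmptyAfterQCError` if no cell survives.
    """
    params = params or QCParams()
    current = matrix
    removed_cells = []
    removed_genes = []
    n_iter = 0
    while True:
        n_iter += 1
        genes_per_cell = current.genes_per_cell()
        umis = current.umis_per_cell()
        mito = current.mito_fraction()
        bad = np.zeros(current.n_cells, bool)
        for reason, mask in [
            ("low_gene_count", genes_per_cell < params.min_genes_per_cell),
            ("high_mito_fraction", mito > params.max_mito_fraction),
            ("high_umi_count", umis > params.max_umis_per_cell),
        ]:
            new = mask & ~bad
            for bc in current.barcodes[new]:
                removed_cells.append((bc, reason))
            bad |= mask
        keep_cells = ~bad
        if not keep_cells.any():
            raise EmptyAfterQCError(
                f"all cells of {matrix.sample_id} removed by QC"
            )
        survivors = current.subset(cell_mask=keep_cells) if bad.any() else current
        cells_expressing = np.asarray((survivors.counts > 0).sum(axis=1)).ravel()
        gene_bad = cells_expressing < params.min_cells_per_gene
        if gene_bad.any():
            removed_genes.extend(survivors.gene_names[gene_bad].tolist())
            survivors = survivors.subset(gene_mask=~gene_bad)
        if not bad.any() and not gene_bad.any():
            break
        current = survivors
    report = QCReport(
        removed_cells=pd.DataFrame(removed_cells, columns=["barcode", "reason"]),
        removed_genes=removed_genes,
        n_iterations=n_iter,
    )
    return current, report


def normalize_log(matrix: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Depth-normalise and log-transform: ``ln(1 + scale_factor * c / total)``."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = matrix.umis_per_cell().astype(float)
    if np.any(totals == 0):
        raise ValueError("cell with zero total counts (run QC first)")
    x = sp.csc_matrix(matrix.counts, dtype=np.float64)
    # scale columns by scale_factor / total, then log1p (zeros stay zero)
    x = x @ sp.diags(scale_factor / totals)
    x.data = np.log1p(x.data)
    return NormalizedMatrix(
        x.tocsr(),
        matrix.gene_names,
        matrix.barcodes,
        scale_factor=scale_factor,
        replicate=matrix.replicate,
        day=matrix.day,
    )


def select_hvg(norm: NormalizedMatrix, n_hvg: int = 2000) -> np.ndarray:
    """Top `n_hvg` genes by variance of log-normalised values.

    Ties broken by gene order; returns gene names in matrix order.
    """
    if n_hvg > norm.n_genes:
        n_hvg = norm.n_genes
    var = _gene_variance(norm.values)
    order = np.argsort(-var, kind="stable")[:n_hvg]
    mask = np.zeros(norm.n_genes, bool)
    mask[order] = True
    return norm.gene_names[mask]


def _gene_variance(values: sp.spmatrix) -> np.ndarray:
    v = sp.csr_matrix(values)
    n = v.shape[1]
    mean = np.asarray(v.mean(axis=1)).ravel()
    sq = np.asarray(v.multiply(v).mean(axis=1)).ravel()
    return np.maximum(sq - mean**2, 0.0) * (n / max(n - 1, 1))


def embed_pca(
    norm: NormalizedMatrix,
    n_hvg: int = 2000,
    n_components: int = 30,
    max_z: float = 10.0,
    hvg: np.ndarray = None,
) -> Embedding:
    """PCA embedding on standardised highly variable genes.

    Genes are z-scored (clipped at ``|z| <= max_z``); the PCA sign convention
    is fixed so the largest-magnitude loading of each component is positive,
    making the embedding deterministic. If `hvg` is given it overrides
    internal selection (used to share one gene set across replicates).
    """
    from sklearn.decomposition import PCA

    if hvg is None:
        hvg = select_hvg(norm, n_hvg)
    sub = norm.subset_genes(list(hvg))
    x = np.asarray(sub.values.todense(), dtype=np.float64).T  # cells x genes
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = np.clip((x - mean) / sd, -max_z, max_z)
    rank = min(z.shape)
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank bound {rank}; truncating"
        )
        n_components = rank
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(z)
    loadings = pca.components_
    # sign convention: largest-magnitude loading positive
    for k in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            coords[:, k] *= -1
    return Embedding(
        coordinates=coords,
        explained_variance=pca.explained_variance_,
        hvg=np.asarray(list(hvg), dtype=object),
        barcodes=sub.barcodes,
        loadings=loadings,
    )
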