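"""QC filter semantics, normalisation identity, PCA embedding."""

import numpy as np
import pytest
import scipy.sparse as sp

from anlagen import QCParams, apply_qc, normalize_log, embed_pca
from anlagen.containers import CountMatrix, NormalizedMatrix
from anlagen.qc import EmptyAfterQCError


def _matrix(counts, gene_prefix="g", mito_genes=0):
    counts = np.asarray(counts)
    genes = [f"mt-{i}" for i in range(mito_genes)] + [
        f"{gene_prefix}{i}" for i in range(counts.shape[0] - mito_genes)
    ]
    barcodes = [f"b{i}" for i in range(counts.shape[1])]
    return CountMatrix(sp.csr_matrix(counts), genes, barcodes)


class TestCellFilters:
    def test_gene_count_boundary(self):
        """A cell with 499 detected genes is removed; 500 is retained."""
        n_genes = 510
        counts = np.zeros((n_genes, 2), dtype=int)
        counts[:499, 0] = 1
        counts[:500, 1] = 1
        m = _matrix(counts)
        params = QCParams(min_cells_per_gene=1)
        filtered, report = apply_qc(m, params)
        assert list(filtered.barcodes) == ["b1"]
        assert report.removed_cells.iloc[0]["reason"] == "low_gene_count"

    def test_mito_fraction_boundary(self):
        """Mito fraction 0.11 removes the cell; exactly 0.10 retains it."""
        n_genes = 600
        counts = np.ones((n_genes, 2), dtype=int)
        # 10 mito genes; totals 1000 -> mito counts 110 vs 100
        counts[:, 0] = 1
        m_counts = counts.copy()
        # cell 0: total 1000, mito 110; cell 1: total 1000, mito 100
        m_counts[:, :] = 0
        m_counts[10:600, 0] = 1  # 590 nuclear genes x1
        m_counts[:10, 0] = [73, 5, 5, 5, 5, 5, 3, 3, 3, 3]  # mito = 110
        m_counts[10:600, 1] = 1
        m_counts[:10, 1] = [63, 5, 5, 5, 5, 5, 3, 3, 3, 3]  # mito = 100
        m_counts[10, 0] += 300  # cell 0: nuclear 890 + mito 110 = 1000 -> 0.11
        m_counts[10, 1] += 310  # cell 1: nuclear 900 + mito 100 = 1000 -> 0.10
        m = _matrix(m_counts, mito_genes=10)
        frac = m.mito_fraction()
        assert frac[0] > 0.10 and abs(frac[1] - 0.10) < 1e-12
        filtered, report = apply_qc(m, QCParams(min_genes_per_cell=100, min_cells_per_gene=1))
        assert list(filtered.barcodes) == ["b1"]
        assert (report.removed_cells["reason"] == "high_mito_fraction").all()

    def test_umi_boundary(self):
        """60 001 total UMIs removes the cell; exactly 60 000 retains it."""
        counts = np.zeros((600, 2), dtype=int)
        counts[:600, 0] = 100
        counts[0, 0] += 1  # 60 001
        counts[:600, 1] = 100  # 60 000
        filtered, report = apply_qc(
            _matrix(counts), QCParams(min_genes_per_cell=100, min_cells_per_gene=1)
        )
        assert list(filtered.barcodes) == ["b1"]
        assert (report.removed_cells["reason"] == "high_umi_count").all()

    def test_empty_after_qc_raises(self):
        counts = np.ones((10, 3), dtype=int)
        with pytest.raises(EmptyAfterQCError):
            apply_qc(_matrix(counts))  # far below 500 genes


class TestFixtureExactness:
    def test_planted_violations_fixture(self):
        """20-cell fixture: 3 planted cell violations plus a gene left in 9 survivors."""
        G = 521  # 520 regular genes + 1 'rare' gene
        n_cells = 20
        counts = np.zeros((G, n_cells), dtype=int)
        counts[:520, :] = 1  # every cell expresses 520 genes once
        # violation 1: only 499 detected genes
        counts[:, 0] = 0
        counts[:499, 0] = 1
        # violation 2: >10% mito (gene 0 is mito below)
        counts[0, 1] = 200  # mito 200 / total 719 -> 27.8%
        # violation 3: >60 000 UMIs
        counts[1, 2] = 60_000
        # rare gene expressed in 9 surviving cells (and in a removed cell)
        counts[520, 2] = 1
        counts[520, 3:12] = 1
        genes = ["mt-0"] + [f"g{i}" for i in range(519)] + ["rare"]
        m = CountMatrix(sp.csr_matrix(counts), genes, [f"b{i}" for i in range(n_cells)])
        filtered, report = apply_qc(m, QCParams())
        assert filtered.n_cells == 17
        assert filtered.n_genes == G - 1
        assert report.removed_genes == ["rare"]
        assert len(report.removed_cells) == 3

    def test_qc_fixed_point_idempotent(self, small_timecourse):
        _, matrices, _ = small_timecourse
        params = QCParams(min_genes_per_cell=300, min_cells_per_gene=10)
        filtered, _ = apply_qc(matrices[0], params)
        again, report2 = apply_qc(filtered, params)
        assert report2.n_cells_removed == 0
        assert report2.removed_genes == []
        assert again.counts.shape == filtered.counts.shape


class TestNormalize:
    def test_stated_formula(self):
        counts = np.zeros((3, 1), dtype=int)
        counts[0, 0] = 20
        counts[1, 0] = 1980
        m = _matrix(counts)
        norm = normalize_log(m, scale_factor=10_000)
        assert norm.values[0, 0] == pytest.approx(np.log(101), abs=1e-12)
        assert norm.values[2, 0] == 0.0  # zero count maps to zero

    def test_conservation_identity(self, small_timecourse):
        _, matrices, _ = small_timecourse
        norm = normalize_log(matrices[1], scale_factor=1e4)
        sums = np.asarray(np.expm1(norm.values.todense()).sum(axis=0)).ravel()
        np.testing.assert_allclose(sums, 1e4, rtol=1e-10)

    def test_zero_total_cell_rejected(self):
        counts = np.zeros((5, 2), dtype=int)
        counts[0, 0] = 3
        with pytest.raises(ValueError, match="zero total"):
            normalize_log(_matrix(counts))


def _norm_from_values(values):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        sp.csr_matrix(values),
        [f"g{i}" for i in range(values.shape[0])],
        [f"b{i}" for i in range(values.shape[1])],
    )


class TestEmbedding:
    def test_variances_non_increasing(self, small_timecourse):
        _, matrices, _ = small_timecourse
        filtered, _ = apply_qc(matrices[0], QCParams(min_genes_per_cell=200))
        emb = embed_pca(normalize_log(filtered), n_hvg=300, n_components=10)
        assert np.all(np.diff(emb.explained_variance) <= 1e-9)

    def test_planar_data_has_zero_trailing_variance(self):
        rng = np.random.default_rng(0)
        basis = rng.uniform(0.5, 1.5, size=(2, 30))
        coeff = rng.uniform(0, 1, size=(40, 2))
        values = (coeff @ basis).T  # 30 genes x 40 cells, rank 2
        emb = embed_pca(_norm_from_values(values), n_hvg=30, n_components=5)
        assert emb.explained_variance[0] > 0
        assert np.all(emb.explained_variance[2:] < 1e-20 * emb.explained_variance[0])

    def test_separated_populations_split_on_first_component(self):
        values = np.zeros((20, 30))
        values[:10, :15] = 3.0  # population 1 expresses genes 0-9
        values[10:, 15:] = 3.0  # population 2 expresses genes 10-19
        emb = embed_pca(_norm_from_values(values), n_hvg=20, n_components=3)
        pc1 = emb.coordinates[:, 0]
        a, b = pc1[:15], pc1[15:]
        assert max(a.max(), b.max()) > min(a.min(), b.min())  # sanity
        assert a.max() < b.min() or b.max() < a.min()  # zero overlap

    def test_too_many_components_warns_and_truncates(self):
        values = np.random.default_rng(1).uniform(0, 2, size=(10, 6))
        with pytest.warns(UserWarning, match="truncating"):
            emb = embed_pca(_norm_from_values(values), n_hvg=10, n_components=50)
        assert emb.n_components <= 6

    def test_gene_permutation_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 4, size=(25, 40))
        norm = _norm_from_values(values)
        emb = embed_pca(norm, n_hvg=25, n_components=4)
        perm = rng.permutation(25)
        permuted = NormalizedMatrix(
            sp.csr_matrix(values[perm]),
            [f"g{i}" for i in perm],
            [f"b{i}" for i in range(40)],
        )
        emb2 = embed_pca(permuted, n_hvg=25, n_components=4)
        np.testing.assert_allclose(emb.coordinates, emb2.coordinates, atol=1e-8)
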