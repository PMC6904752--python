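"""Centroid rank correlation, matching/discard, families, pooling, final clustering."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy import stats

from anlagen import (
    ClusterParams,
    CentroidSet,
    CorrelationMap,
    cluster_cells,
    centroid_rank_correlation,
    match_and_discard,
    consolidate_families,
    pool_and_correct,
    final_cluster,
    diagonal_dominance,
    consolidate_timecourse,
)
from anlagen.consolidate import MatchResult, _reciprocal_best_pairs, _hungarian_pairs
from anlagen.containers import Embedding, NormalizedMatrix


def _embedding(coords):
    coords = np.asarray(coords, float)
    var = np.sort(np.var(coords, axis=0))[::-1]
    return Embedding(coords, var, hvg=np.array([]), barcodes=np.array([f"b{i}" for i in range(len(coords))], dtype=object))


def _centroids(matrix, sample_id="s"):
    matrix = np.asarray(matrix, float)
    return CentroidSet(
        matrix,
        genes=np.array([f"g{i}" for i in range(matrix.shape[1])], dtype=object),
        sizes=np.full(matrix.shape[0], 10),
        sample_id=sample_id,
    )


class TestClusterCells:
    def test_separated_blobs_recovered_exactly(self):
        coords = np.vstack([np.tile([0.0, 0.0], (20, 1)), np.tile([10.0, 10.0], (15, 1))])
        cl = cluster_cells(_embedding(coords), ClusterParams(k=2, seed=0))
        labels = cl.labels
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]
        # contiguous labels, largest cluster first
        assert labels[0] == 0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(60, 5))
        a = cluster_cells(_embedding(coords), ClusterParams(k=4, seed=3)).labels
        b = cluster_cells(_embedding(coords), ClusterParams(k=4, seed=3)).labels
        np.testing.assert_array_equal(a, b)

    def test_more_clusters_than_cells_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_cells(_embedding(np.zeros((3, 2))), ClusterParams(k=5))


class TestRankCorrelation:
    def test_self_correlation_diagonal_is_one(self):
        rng = np.random.default_rng(0)
        a = _centroids(rng.uniform(size=(4, 50)))
        cm = centroid_rank_correlation(a, a)
        np.testing.assert_allclose(np.diag(cm.rho), 1.0, atol=1e-12)

    def test_rank_reversal_gives_minus_one(self):
        v = np.arange(20.0)
        cm = centroid_rank_correlation(_centroids(v[None, :]), _centroids(v[::-1][None, :]))
        assert cm.rho[0, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_four_gene_example(self):
        cm = centroid_rank_correlation(
            _centroids([[1, 2, 3, 4]]), _centroids([[1, 3, 2, 4]])
        )
        assert cm.rho[0, 0] == pytest.approx(0.8, abs=1e-12)

    def test_matches_scipy_spearman_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            x = rng.normal(size=40)
            y = rng.normal(size=40)
            cm = centroid_rank_correlation(_centroids(x[None]), _centroids(y[None]))
            expected = stats.spearmanr(x, y).statistic
            assert cm.rho[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = _centroids(rng.uniform(size=(3, 30)), "a")
        b = _centroids(rng.uniform(size=(5, 30)), "b")
        np.testing.assert_allclose(
            centroid_rank_correlation(a, b).rho,
            centroid_rank_correlation(b, a).rho.T,
            atol=1e-14,
        )

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0.1, 2.0, size=(2, 25))
        b = rng.uniform(0.1, 2.0, size=(2, 25))
        base = centroid_rank_correlation(_centroids(a), _centroids(b)).rho
        warped = centroid_rank_correlation(
            _centroids(np.exp(a)), _centroids(b**3)
        ).rho
        np.testing.assert_allclose(base, warped, atol=1e-12)

    def test_gene_set_mismatch_rejected(self):
        a = _centroids(np.ones((1, 5)) * np.arange(5))
        b = CentroidSet(np.ones((1, 5)), genes=np.array([f"x{i}" for i in range(5)], dtype=object), sizes=np.array([3]))
        with pytest.raises(ValueError, match="gene set"):
            centroid_rank_correlation(a, b)

    def test_zero_variance_centroid_is_nan_with_warning(self):
        a = _centroids(np.vstack([np.ones(10), np.arange(10.0)]))
        b = _centroids(np.arange(10.0)[None])
        with pytest.warns(UserWarning, match="zero-variance"):
            cm = centroid_rank_correlation(a, b)
        assert np.isnan(cm.rho[0, 0])
        assert np.isfinite(cm.rho[1, 0])


def _map_from_rho(rho, a="sa", b="sb"):
    return CorrelationMap(np.asarray(rho, float), a, b)


class TestMatchAndDiscard:
    def test_permutation_recovered_nothing_discarded(self):
        rng = np.random.default_rng(1)
        cents = rng.uniform(size=(4, 60))
        perm = [2, 0, 3, 1]
        a = _centroids(cents, "sa")
        b = _centroids(cents[perm], "sb")
        cm = centroid_rank_correlation(a, b)
        result = match_and_discard([cm], min_rho=0.5)
        assert sorted(cm.matching) == [(0, 1), (1, 3), (2, 0), (3, 2)]
        assert result.discarded == set()

    def test_planted_uncorrelated_cluster_discarded(self):
        rng = np.random.default_rng(2)
        shared = rng.uniform(size=(3, 80))
        private = rng.uniform(size=(1, 80))
        a = _centroids(np.vstack([shared, private]), "sa")
        b = _centroids(shared + rng.normal(0, 0.01, size=shared.shape), "sb")
        result = match_and_discard([centroid_rank_correlation(a, b)], min_rho=0.5)
        assert result.discarded == {("sa", 3)}

    def test_non_reciprocal_cluster_flagged_unmatched(self):
        rho = np.array(
            [
                [0.95, 0.10, 0.20],
                [0.10, 0.90, 0.30],
                [0.94, 0.40, 0.35],  # best match (col 0) already taken by row 0
            ]
        )
        cm = _map_from_rho(rho)
        pairs = _reciprocal_best_pairs(rho, min_rho=0.5)
        assert sorted(pairs) == [(0, 0), (1, 1)]
        match_and_discard([cm], min_rho=0.5)
        assert cm.unmatched_a == {2}
        assert cm.unmatched_b == {2}

    def test_hungarian_backend_agrees_on_clean_map(self):
        rho = np.eye(4) * 0.9 + 0.05
        assert sorted(_hungarian_pairs(rho, 0.5)) == sorted(
            _reciprocal_best_pairs(rho, 0.5)
        )

    def test_empty_map_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            match_and_discard([], min_rho=0.5)


class TestConsolidateFamilies:
    def _result(self, maps):
        return match_and_discard(maps, min_rho=0.5)

    def test_three_replicates_four_families(self):
        rng = np.random.default_rng(3)
        cents = rng.uniform(size=(4, 60))
        sets = {s: _centroids(cents, s) for s in ["r1", "r2", "r3"]}
        maps = [
            centroid_rank_correlation(sets[a], sets[b])
            for a, b in [("r1", "r2"), ("r1", "r3"), ("r2", "r3")]
        ]
        result = self._result(maps)
        sizes = {(s, c): 10 for s in sets for c in range(4)}
        fam = consolidate_families(result, sizes)
        assert len(set(fam.assignments.values())) == 4
        from collections import Counter

        assert set(Counter(fam.assignments.values()).values()) == {3}

    def test_chain_is_transitively_one_family(self):
        maps = []
        m1 = _map_from_rho([[0.9]], "r1", "r2")
        m2 = _map_from_rho([[0.9]], "r2", "r3")
        result = match_and_discard([m1, m2], min_rho=0.5, within_day={"r1": 0, "r2": 0, "r3": 0})
        sizes = {("r1", 0): 5, ("r2", 0): 5, ("r3", 0): 5}
        fam = consolidate_families(result, sizes)
        assert len(set(fam.assignments.values())) == 1

    def test_conflict_split_cuts_weaker_edge(self):
        # r1 has two clusters; both link into one component through r2c0:
        # r1c0 -0.9- r2c0 -0.6- r1c1. The weaker edge must be cut.
        m1 = CorrelationMap(np.array([[0.9], [0.0]]), "r1", "r2")
        m1.matching = [(0, 0)]
        m2 = CorrelationMap(np.array([[0.0], [0.6]]), "r1", "r2b")
        m2.matching = [(1, 0)]
        m3 = CorrelationMap(np.array([[0.7]]), "r2", "r2b")
        m3.matching = [(0, 0)]
        result = MatchResult(maps=[m1, m2, m3], discarded=set(), match_stats=None)
        sizes = {("r1", 0): 10, ("r1", 1): 8, ("r2", 0): 10, ("r2b", 0): 9}
        fam = consolidate_families(result, sizes)
        groups = {}
        for node, f in fam.assignments.items():
            groups.setdefault(f, set()).add(node)
        assert {("r1", 0), ("r2", 0), ("r2b", 0)} in groups.values()
        assert {("r1", 1)} in groups.values()
        assert fam.conflicts and fam.conflicts[0][1] == pytest.approx(0.6)

    def test_family_names_ordered_by_total_size(self):
        m = _map_from_rho([[0.9, 0.0], [0.0, 0.8]], "r1", "r2")
        result = match_and_discard([m], min_rho=0.5)
        sizes = {("r1", 0): 5, ("r1", 1): 50, ("r2", 0): 5, ("r2", 1): 60}
        fam = consolidate_families(result, sizes)
        assert fam.assignments[("r1", 1)] == "A"
        assert fam.assignments[("r1", 0)] == "B"


def _norm(values, replicate="r1", day=0, prefix="b"):
    values = np.asarray(values, float)
    return NormalizedMatrix(
        sp.csr_matrix(values),
        [f"g{i}" for i in range(values.shape[0])],
        [f"{prefix}{i}" for i in range(values.shape[1])],
        replicate=replicate,
        day=day,
    )


class TestPoolAndCorrect:
    def test_single_batch_identity(self):
        rng = np.random.default_rng(0)
        nm = _norm(rng.uniform(0, 3, size=(10, 8)))
        merged = pool_and_correct([nm])
        np.testing.assert_allclose(
            merged.corrected, np.asarray(nm.values.todense()), atol=1e-14
        )

    def test_constant_offset_removed_exactly(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(1, 3, size=(12, 10))
        offset = rng.uniform(0.1, 0.5, size=(12, 1))
        a = _norm(base, "r1", prefix="a")
        b = _norm(base + offset, "r2", prefix="b")
        merged = pool_and_correct([a, b])
        for batch in np.unique(merged.batches):
            batch_means = merged.corrected[:, merged.batches == batch].mean(axis=1)
            np.testing.assert_allclose(
                batch_means, merged.corrected.mean(axis=1), atol=1e-12
            )

    def test_batch_label_length_mismatch_rejected(self):
        nm = _norm(np.ones((4, 5)))
        with pytest.raises(ValueError, match="label count"):
            pool_and_correct([nm], batch_labels=["x", "y"])

    def test_tiny_batch_excluded_with_warning(self):
        a = _norm(np.random.default_rng(2).uniform(0, 2, (6, 5)), "r1", prefix="a")
        b = _norm(np.ones((6, 1)), "r2", prefix="z")
        with pytest.warns(UserWarning, match="fewer than 2"):
            merged = pool_and_correct([a, b])
        assert merged.n_cells == 5


class TestFinalCluster:
    def test_noise_free_families_recovered_perfectly(self, noise_free_result):
        from sklearn.metrics import adjusted_rand_score

        res, truth = noise_free_result
        tc = truth.cells.set_index("barcode")
        tab = res.cell_table
        ari = adjusted_rand_score(
            tc.loc[tab.barcode, "family"], tab["final_family"].astype(str)
        )
        assert res.n_families == 7
        assert ari == 1.0

    def test_contribution_rows_sum_to_cluster_sizes(self, noise_free_result):
        res, _ = noise_free_result
        by_cluster = res.contribution.groupby("final_cluster")["n_cells"].sum()
        sizes = {c: int((res.final_labels == c).sum()) for c in set(res.final_labels)}
        assert dict(by_cluster) == sizes

    def test_family_assignment_stable_under_relabeling(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 2, size=(20, 30))
        a = _norm(values, "r1", prefix="a")
        merged = pool_and_correct([a])
        fams = np.array(["X"] * 15 + ["Y"] * 15, dtype=object)
        labels, fam_of, _ = final_cluster(merged, ClusterParams(k=2, seed=0), cell_families=fams)
        labels2, fam_of2, _ = final_cluster(merged, ClusterParams(k=2, seed=7), cell_families=fams)
        mapped = [fam_of[int(c)] for c in labels]
        mapped2 = [fam_of2[int(c)] for c in labels2]
        # same kmeans partition under either seed -> same family per cell
        assert mapped == mapped2


class TestDiagonalDominance:
    def test_identity_map_is_one(self):
        cm = _map_from_rho(np.eye(3))
        frac, off = diagonal_dominance(cm, matching=[(i, i) for i in range(3)])
        assert frac == 1.0
        assert all(v < 1 for v in off.values())

    def test_single_off_match_row_gives_three_quarters(self):
        rho = np.eye(4) * 0.9
        rho[2, 3] = 0.95  # row 2's maximum is off its match
        frac, off = diagonal_dominance(_map_from_rho(rho), matching=[(i, i) for i in range(4)])
        assert frac == 0.75
        assert off[2] == pytest.approx(0.95)

    def test_noise_free_replicate_pair_is_one(self, noise_free_result):
        res, _ = noise_free_result
        assert (res.diagnostics["diagonal_dominance"] == 1.0).all()

    def test_empty_matching_rejected(self):
        with pytest.raises(ValueError, match="empty matching"):
            diagonal_dominance(_map_from_rho(np.eye(2)), matching=[])
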