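"""Cluster consolidation across replicates and timepoints.

The procedure: cluster each replicate unsupervised into provisional clusters;
summarise each cluster by its centroid (mean log-normalised expression over a
shared highly-variable gene set); Spearman rank-correlate centroid sets within
and between timepoints; match clusters by reciprocal best correlation above a
threshold; discard provisional clusters that fail to align in their
within-timepoint comparisons; take connected components of the match graph as
cell families; pool retained cells, centre out the per-batch gene means, and
run a final unsupervised clustering whose clusters inherit family labels by
plurality.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .containers import NormalizedMatrix, MergedMatrix, Embedding
from .qc import apply_qc, normalize_log, embed_pca, QCParams, _gene_variance


# ---------------------------------------------------------------------------
# Provisional clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterParams:
    """Unsupervised clustering configuration.

    Two interchangeable backends: ``"kmeans"`` with fixed `k`, or ``"leiden"``
    graph/community clustering at `resolution` on a `n_neighbors`-NN graph.
    """

    method: str = "kmeans"
    k: int = 7
    resolution: float = 1.0
    n_neighbors: int = 15
    seed: int = 0


@dataclass
class ProvisionalClustering:
    """Per-cell integer labels for one replicate, contiguous from 0."""

    labels: np.ndarray
    replicate: str
    day: int
    params: ClusterParams
    barcodes: np.ndarray = None

    @property
    def sample_id(self) -> str:
        return f"d{self.day}-{self.replicate}"

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def cluster_cells(
    embedding: Embedding, params: ClusterParams = None, replicate: str = "r1", day: int = 0
) -> ProvisionalClustering:
    """Cluster cells of one embedding; deterministic given ``params.seed``."""
    params = params or ClusterParams()
    n = embedding.n_cells
    if params.method == "kmeans":
        if params.k > n:
            raise ValueError(f"k={params.k} exceeds number of cells {n}")
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=params.k, n_init=10, random_state=params.seed)
        labels = km.fit_predict(embedding.coordinates)
    elif params.method == "leiden":
        labels = _leiden_labels(embedding.coordinates, params)
    else:
        raise ValueError(f"unknown clustering method {params.method!r}")
    labels = _contiguous_by_size(labels)
    return ProvisionalClustering(
        labels=labels,
        replicate=replicate,
        day=day,
        params=params,
        barcodes=embedding.barcodes,
    )


def _contiguous_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 in order of decreasing size (stable)."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(l)] for l in labels], dtype=int)


def _leiden_labels(coords: np.ndarray, params: ClusterParams) -> np.ndarray:
    import igraph
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    k = min(params.n_neighbors, coords.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    g = igraph.Graph(n=coords.shape[0], edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=params.resolution,
        seed=params.seed,
    )
    return np.asarray(part.membership, dtype=int)


# ---------------------------------------------------------------------------
# Centroids and rank correlation
# ---------------------------------------------------------------------------


@dataclass
class CentroidSet:
    """Per-cluster mean log-normalised expression over a shared gene set."""

    centroids: np.ndarray  # clusters x genes
    genes: np.ndarray
    sizes: np.ndarray
    sample_id: str = ""

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]


def compute_centroids(
    norm: NormalizedMatrix, labels: np.ndarray, genes
) -> CentroidSet:
    """Mean expression per cluster, restricted to `genes` (shared HVG set)."""
    sub = norm.subset_genes(list(genes))
    x = sub.values  # genes x cells sparse
    labels = np.asarray(labels)
    k = int(labels.max()) + 1
    cents = np.zeros((k, len(sub.gene_names)))
    sizes = np.zeros(k, dtype=int)
    for c in range(k):
        mask = labels == c
        sizes[c] = mask.sum()
        if sizes[c]:
            cents[c] = np.asarray(x[:, mask].mean(axis=1)).ravel()
    return CentroidSet(cents, sub.gene_names, sizes, sample_id=norm.sample_id)


@dataclass
class CorrelationMap:
    """Spearman correlations between two centroid sets plus an optional matching."""

    rho: np.ndarray  # clusters_a x clusters_b
    sample_a: str
    sample_b: str
    matching: list = None  # list of (i, j) reciprocal-best pairs
    unmatched_a: set = None
    unmatched_b: set = None


def centroid_rank_correlation(a: CentroidSet, b: CentroidSet) -> CorrelationMap:
    """Spearman rho between every centroid of `a` and every centroid of `b`.

    Uses average ranks for ties. A zero-variance centroid yields undefined
    correlations, reported as NaN with a warning.
    """
    if list(a.genes) != list(b.genes):
        raise ValueError("centroid sets must share an identically ordered gene set")
    ra = np.apply_along_axis(rankdata, 1, a.centroids)
    rb = np.apply_along_axis(rankdata, 1, b.centroids)
    rho = _pearson_cross(ra, rb)
    if np.isnan(rho).any():
        warnings.warn("zero-variance centroid: correlation undefined (NaN)")
    return CorrelationMap(rho, a.sample_id, b.sample_id)


def _pearson_cross(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise cross Pearson correlation matrix between x (m,g) and y (n,g)."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1))
    ys = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (xc @ yc.T) / np.outer(xs, ys)
    rho[~np.isfinite(rho)] = np.nan
    return np.clip(rho, -1.0, 1.0, out=rho)


# ---------------------------------------------------------------------------
# Matching, discard, families
# ---------------------------------------------------------------------------


def _reciprocal_best_pairs(rho: np.ndarray, min_rho: float) -> list:
    """Pairs (i, j) where i is j's argmax, j is i's argmax, and rho >= min_rho."""
    if rho.size == 0:
        return []
    safe = np.where(np.isnan(rho), -np.inf, rho)
    best_b = safe.argmax(axis=1)
    best_a = safe.argmax(axis=0)
    pairs = []
    for i in range(rho.shape[0]):
        j = best_b[i]
        if best_a[j] == i and safe[i, j] >= min_rho:
            pairs.append((i, int(j)))
    return pairs


def _hungarian_pairs(rho: np.ndarray, min_rho: float) -> list:
    """Globally optimal assignment backend (for sensitivity analysis)."""
    from scipy.optimize import linear_sum_assignment

    safe = np.where(np.isnan(rho), -1.0, rho)
    rows, cols = linear_sum_assignment(-safe)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if safe[i, j] >= min_rho]


@dataclass
class MatchResult:
    """Per-comparison matchings and the per-cluster discard flags."""

    maps: list  # CorrelationMap with matching filled in
    discarded: set  # (sample_id, cluster index)
    match_stats: pd.DataFrame  # sample, cluster, n_comparisons, n_matched

    def is_discarded(self, sample_id: str, cluster: int) -> bool:
        return (sample_id, cluster) in self.discarded


def match_and_discard(
    corr_maps: list,
    min_rho: float = 0.5,
    require_fraction: float = 1.0,
    within_day: dict = None,
    method: str = "reciprocal",
) -> MatchResult:
    """Match clusters by reciprocal best correlation; flag non-aligning ones.

    A provisional cluster is discarded when it obtains a reciprocal match
    (rho >= `min_rho`) in fewer than ``require_fraction`` of its
    within-timepoint comparisons (default: it must match in all of them).
    `within_day` maps ``sample_id -> day``; when omitted, all comparisons
    count toward the discard rule.
    """
    if not corr_maps:
        raise ValueError("empty correlation map list")
    pair_fn = _hungarian_pairs if method == "hungarian" else _reciprocal_best_pairs
    comparisons = {}
    matched = {}
    for cmap in corr_maps:
        pairs = pair_fn(cmap.rho, min_rho)
        cmap.matching = pairs
        cmap.unmatched_a = set(range(cmap.rho.shape[0])) - {i for i, _ in pairs}
        cmap.unmatched_b = set(range(cmap.rho.shape[1])) - {j for _, j in pairs}
        same_day = (
            within_day is None
            or within_day.get(cmap.sample_a) == within_day.get(cmap.sample_b)
        )
        if not same_day:
            continue
        for i in range(cmap.rho.shape[0]):
            key = (cmap.sample_a, i)
            comparisons[key] = comparisons.get(key, 0) + 1
            matched.setdefault(key, 0)
        for j in range(cmap.rho.shape[1]):
            key = (cmap.sample_b, j)
            comparisons[key] = comparisons.get(key, 0) + 1
            matched.setdefault(key, 0)
        for i, j in pairs:
            matched[(cmap.sample_a, i)] += 1
            matched[(cmap.sample_b, j)] += 1
    discarded = {
        key
        for key, n in comparisons.items()
        if matched[key] < np.ceil(require_fraction * n) - 1e-9
    }
    stats = pd.DataFrame(
        [
            (s, c, comparisons[(s, c)], matched[(s, c)], (s, c) in discarded)
            for (s, c) in sorted(comparisons)
        ],
        columns=["sample", "cluster", "n_comparisons", "n_matched", "discarded"],
    )
    return MatchResult(maps=corr_maps, discarded=discarded, match_stats=stats)


@dataclass
class FamilyMap:
    """Mapping (sample_id, provisional cluster) -> family label, plus discards."""

    assignments: dict
    discarded: set
    conflicts: list = field(default_factory=list)

    @property
    def families(self) -> list:
        return sorted(set(self.assignments.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s, c, fam) for (s, c), fam in sorted(self.assignments.items())
        ] + [(s, c, "<discarded>") for (s, c) in sorted(self.discarded)]
        return pd.DataFrame(rows, columns=["sample", "cluster", "family"])


def _first_conflict(tree):
    """A pair of same-sample nodes sharing a tree component, or None."""
    import networkx as nx

    for comp in nx.connected_components(tree):
        by_sample = {}
        for node in sorted(comp):
            s = node[0]
            if s in by_sample:
                return by_sample[s], node
            by_sample[s] = node
    return None


def _family_names(n: int) -> list:
    letters = string.ascii_uppercase
    names = []
    for i in range(n):
        name = ""
        j = i
        while True:
            name = letters[j % 26] + name
            j = j // 26 - 1
            if j < 0:
                break
        names.append(name)
    return names


def consolidate_families(match_result: MatchResult, cluster_sizes: dict) -> FamilyMap:
    """Families = connected components of the reciprocal-match graph.

    `cluster_sizes` maps ``(sample_id, cluster) -> n_cells``; family labels
    are assigned A, B, C... in order of decreasing total cell count. A
    component containing two clusters of the same sample is a conflict and is
    split by removing its weakest edges until consistent.
    """
    import networkx as nx

    g = nx.Graph()
    for (sample, c) in cluster_sizes:
        if (sample, c) not in match_result.discarded:
            g.add_node((sample, c))
    for cmap in match_result.maps:
        for i, j in cmap.matching or []:
            u, v = (cmap.sample_a, i), (cmap.sample_b, j)
            if u in g and v in g and u != v:
                g.add_edge(u, v, rho=float(cmap.rho[i, j]))

    # Split any component holding two clusters of one sample. The component is
    # reduced to its maximum spanning tree (strongest edges kept) and, for each
    # conflicting same-sample pair, the weakest edge on the tree path between
    # them is cut — a single-linkage-style split along the strongest backbone.
    conflicts = []
    for comp in list(nx.connected_components(g)):
        samples = [s for s, _ in comp]
        if len(samples) == len(set(samples)):
            continue
        sub = g.subgraph(comp).copy()
        tree = nx.maximum_spanning_tree(sub, weight="rho")
        g.remove_edges_from(sub.edges)
        while True:
            pair = _first_conflict(tree)
            if pair is None:
                break
            path = nx.shortest_path(tree, pair[0], pair[1])
            path_edges = list(zip(path[:-1], path[1:]))
            rho_min, edge = min(
                (tree.edges[e]["rho"], e) for e in path_edges
            )
            conflicts.append((edge, rho_min))
            tree.remove_edge(*edge)
        g.add_edges_from(tree.edges(data=True))

    comps = sorted(
        nx.connected_components(g),
        key=lambda comp: (-sum(cluster_sizes.get(n, 0) for n in comp), sorted(comp)),
    )
    names = _family_names(len(comps))
    assignments = {}
    for name, comp in zip(names, comps):
        for node in comp:
            assignments[node] = name
    return FamilyMap(assignments=assignments, discarded=set(match_result.discarded), conflicts=conflicts)


# ---------------------------------------------------------------------------
# Pooling, batch correction, final clustering
# ---------------------------------------------------------------------------


def pool_and_correct(matrices: list, batch_labels: list = None) -> MergedMatrix:
    """Pool cells from all samples and centre out per-batch gene means.

    Gene set is the intersection (in first-matrix order). Each batch's
    per-gene mean is shifted to the pooled per-gene mean; corrected values are
    stored alongside the originals. Batches with fewer than 2 cells are
    excluded with a warning.
    """
    if not matrices:
        raise ValueError("no matrices to pool")
    if batch_labels is None:
        batch_labels = [m.sample_id for m in matrices]
    if len(batch_labels) != len(matrices):
        raise ValueError("batch label count != matrix count")
    kept = []
    for m, b in zip(matrices, batch_labels):
        if m.n_cells < 2:
            warnings.warn(f"batch {b} has fewer than 2 cells; excluded")
        else:
            kept.append((m, b))
    if not kept:
        raise ValueError("no batch with >= 2 cells")
    shared = list(kept[0][0].gene_names)
    shared_set = set(shared)
    for m, _ in kept[1:]:
        shared_set &= set(m.gene_names)
    shared = [g for g in shared if g in shared_set]
    if not shared:
        raise ValueError("empty gene intersection across batches")

    subs = [m.subset_genes(shared) for m, _ in kept]
    values = sp.hstack([s.values for s in subs], format="csr")
    barcodes = np.concatenate([s.barcodes for s in subs])
    batches = np.concatenate(
        [np.full(s.n_cells, b, dtype=object) for s, (_, b) in zip(subs, kept)]
    )
    days = np.concatenate([np.full(s.n_cells, s.day) for s in subs])
    replicates = np.concatenate(
        [np.full(s.n_cells, s.replicate, dtype=object) for s in subs]
    )
    if len(set(barcodes)) != len(barcodes):
        barcodes = np.array(
            [f"{b}:{bc}" for b, bc in zip(batches, barcodes)], dtype=object
        )

    dense = np.asarray(values.todense())
    global_mean = dense.mean(axis=1, keepdims=True)
    corrected = dense.copy()
    for b in pd.unique(batches):
        mask = batches == b
        batch_mean = dense[:, mask].mean(axis=1, keepdims=True)
        corrected[:, mask] += global_mean - batch_mean
    return MergedMatrix(
        values=values,
        corrected=corrected,
        gene_names=np.asarray(shared, dtype=object),
        barcodes=barcodes,
        batches=batches,
        days=days,
        replicates=replicates,
        scale_factor=kept[0][0].scale_factor,
    )


def final_cluster(
    merged: MergedMatrix,
    params: ClusterParams,
    cell_families: np.ndarray = None,
    n_components: int = 30,
    hvg: np.ndarray = None,
):
    """Supplemental unsupervised clustering of the batch-corrected merged set.

    Returns ``(labels, family_of_cluster, contribution)``: per-cell final
    cluster labels; a mapping final cluster -> family by plurality of
    `cell_families` (None entries ignored; mapping empty when no families
    given); and the per-(day, replicate) contribution table of each cluster.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    if hvg is not None:
        idx = {g: i for i, g in enumerate(merged.gene_names)}
        rows = np.array([idx[g] for g in hvg if g in idx])
        x = merged.corrected[rows, :].T
    else:
        x = merged.corrected.T
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = np.clip((x - mean) / sd, -10, 10)
    n_components = min(n_components, min(z.shape))
    coords = PCA(n_components=n_components, svd_solver="full").fit_transform(z)
    emb = Embedding(
        coordinates=coords,
        explained_variance=np.sort(np.var(coords, axis=0))[::-1],
        hvg=merged.gene_names if hvg is None else np.asarray(list(hvg), dtype=object),
        barcodes=merged.barcodes,
    )
    clustering = cluster_cells(emb, params)
    labels = clustering.labels

    family_of_cluster = {}
    if cell_families is not None:
        cell_families = np.asarray(cell_families, dtype=object)
        for c in range(labels.max() + 1):
            fams = cell_families[labels == c]
            fams = fams[fams != None]  # noqa: E711
            if len(fams):
                uniq, counts = np.unique(fams.astype(str), return_counts=True)
                family_of_cluster[c] = uniq[np.argmax(counts)]

    contribution = (
        pd.DataFrame(
            {
                "final_cluster": labels,
                "day": merged.days,
                "replicate": merged.replicates,
            }
        )
        .groupby(["final_cluster", "day", "replicate"])
        .size()
        .rename("n_cells")
        .reset_index()
    )
    return labels, family_of_cluster, contribution


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def diagonal_dominance(corr: CorrelationMap, matching: list = None):
    """Fraction of matched clusters whose partner is the strict row maximum.

    Also returns, per matched row, the maximum off-match correlation (to
    surface secondary affinities between related families). Returns
    ``(fraction, off_diagonal_max)``.
    """
    matching = matching if matching is not None else corr.matching
    if not matching:
        raise ValueError("empty matching: diagonal dominance undefined")
    safe = np.where(np.isnan(corr.rho), -np.inf, corr.rho)
    dominant = 0
    off_max = {}
    for i, j in matching:
        row = safe[i]
        others = np.delete(row, j)
        off = others.max() if others.size else -np.inf
        off_max[i] = float(off)
        if row[j] > off:
            dominant += 1
    return dominant / len(matching), off_max


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class ConsolidationResult:
    """Everything the consolidation pipeline produced.

    ``cell_table`` has one row per retained cell: barcode, day, replicate,
    provisional cluster, family (from the match graph), final cluster and
    final family (from the merged clustering).
    """

    family_map: FamilyMap
    match_result: MatchResult
    correlation_maps: dict
    merged: MergedMatrix
    final_labels: np.ndarray
    family_of_final_cluster: dict
    contribution: pd.DataFrame
    cell_table: pd.DataFrame
    hvg: np.ndarray
    diagnostics: pd.DataFrame

    @property
    def n_families(self) -> int:
        return len(set(self.family_map.assignments.values()))

    def summary(self) -> str:
        lines = [
            "Cluster consolidation summary",
            "=============================",
            f"families recovered: {self.n_families} "
            f"({', '.join(sorted(set(self.family_map.assignments.values())))})",
            f"provisional clusters discarded: {len(self.family_map.discarded)}",
            f"retained cells in merged set: {self.merged.n_cells}",
            "",
            "within-timepoint diagonal dominance:",
        ]
        for _, row in self.diagnostics.iterrows():
            lines.append(
                f"  {row['sample_a']} vs {row['sample_b']}: {row['diagonal_dominance']:.3f}"
            )
        return "\n".join(lines)


def consolidate_timecourse(
    matrices: list,
    qc_params: QCParams = None,
    n_hvg: int = 2000,
    n_components: int = 30,
    cluster_params: ClusterParams = None,
    min_rho: float = 0.5,
    require_fraction: float = 1.0,
    final_k: int = None,
    seed: int = 0,
) -> ConsolidationResult:
    """Run the full consolidation pipeline on raw per-replicate count matrices.

    QC and normalisation per replicate; a shared HVG set (top `n_hvg` by summed
    per-replicate variance over the gene intersection); per-replicate PCA and
    provisional clustering; centroid rank correlation for every pair of
    samples; reciprocal-best matching with the within-timepoint discard rule;
    family consolidation by connected components; pooling of retained cells
    with per-batch gene-mean centring; and a final clustering with `final_k`
    clusters (default: the number of families found).
    """
    cluster_params = cluster_params or ClusterParams(seed=seed)
    norms = []
    for m in matrices:
        filtered, _ = apply_qc(m, qc_params)
        norms.append(normalize_log(filtered))

    # shared HVG set over the gene intersection
    shared = list(norms[0].gene_names)
    shared_set = set(shared)
    for nm in norms[1:]:
        shared_set &= set(nm.gene_names)
    shared = [g for g in shared if g in shared_set]
    var_sum = np.zeros(len(shared))
    for nm in norms:
        sub = nm.subset_genes(shared)
        var_sum += _gene_variance(sub.values)
    order = np.argsort(-var_sum, kind="stable")[: min(n_hvg, len(shared))]
    hvg_mask = np.zeros(len(shared), bool)
    hvg_mask[order] = True
    hvg = np.asarray(shared, dtype=object)[hvg_mask]

    clusterings = {}
    centroids = {}
    for nm in norms:
        emb = embed_pca(nm, n_components=n_components, hvg=hvg)
        cl = cluster_cells(emb, cluster_params, replicate=nm.replicate, day=nm.day)
        clusterings[nm.sample_id] = cl
        centroids[nm.sample_id] = compute_centroids(nm, cl.labels, hvg)

    sample_ids = [nm.sample_id for nm in norms]
    day_of = {nm.sample_id: nm.day for nm in norms}
    corr_maps = {}
    for a, b in itertools.combinations(sample_ids, 2):
        corr_maps[(a, b)] = centroid_rank_correlation(centroids[a], centroids[b])

    match_result = match_and_discard(
        list(corr_maps.values()),
        min_rho=min_rho,
        require_fraction=require_fraction,
        within_day=day_of,
    )
    cluster_sizes = {
        (sid, c): int((clusterings[sid].labels == c).sum())
        for sid in sample_ids
        for c in range(clusterings[sid].n_clusters)
    }
    family_map = consolidate_families(match_result, cluster_sizes)

    # keep only cells of retained provisional clusters
    retained_norms = []
    cell_rows = []
    for nm in norms:
        cl = clusterings[nm.sample_id]
        keep = np.array(
            [(nm.sample_id, int(l)) in family_map.assignments for l in cl.labels]
        )
        if not keep.any():
            continue
        sub = NormalizedMatrix(
            nm.values[:, keep],
            nm.gene_names,
            nm.barcodes[keep],
            scale_factor=nm.scale_factor,
            replicate=nm.replicate,
            day=nm.day,
        )
        retained_norms.append(sub)
        for bc, l in zip(nm.barcodes[keep], cl.labels[keep]):
            cell_rows.append(
                (
                    bc,
                    nm.day,
                    nm.replicate,
                    nm.sample_id,
                    int(l),
                    family_map.assignments[(nm.sample_id, int(l))],
                )
            )
    cell_table = pd.DataFrame(
        cell_rows,
        columns=["barcode", "day", "replicate", "sample", "provisional_cluster", "family"],
    )

    merged = pool_and_correct(retained_norms)
    n_fam = len(set(family_map.assignments.values()))
    fk = final_k or n_fam
    final_params = ClusterParams(
        method=cluster_params.method,
        k=fk,
        resolution=cluster_params.resolution,
        n_neighbors=cluster_params.n_neighbors,
        seed=cluster_params.seed,
    )
    final_labels, fam_of_cluster, contribution = final_cluster(
        merged,
        final_params,
        cell_families=cell_table["family"].to_numpy(),
        n_components=n_components,
        hvg=hvg,
    )
    cell_table["final_cluster"] = final_labels
    cell_table["final_family"] = [fam_of_cluster.get(int(c)) for c in final_labels]

    diag_rows = []
    for (a, b), cmap in corr_maps.items():
        if day_of[a] == day_of[b] and cmap.matching:
            frac, _ = diagonal_dominance(cmap)
            diag_rows.append((a, b, frac))
    diagnostics = pd.DataFrame(
        diag_rows, columns=["sample_a", "sample_b", "diagonal_dominance"]
    )
    return ConsolidationResult(
        family_map=family_map,
        match_result=match_result,
        correlation_maps=corr_maps,
        merged=merged,
        final_labels=final_labels,
        family_of_final_cluster=fam_of_cluster,
        contribution=contribution,
        cell_table=cell_table,
        hvg=hvg,
        diagnostics=diagnostics,
    )
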