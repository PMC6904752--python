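"""Cluster-vs-rest marker statistics, identity assignment, timecourse heatmaps.

Fold changes are reported on the linear (ratio) scale computed from
back-transformed (``expm1``) normalised expression; p-values come from a
two-sided Wilcoxon rank-sum test on log values (config-switchable to Welch's
t) with Benjamini–Hochberg FDR adjustment across genes within each
cluster-vs-rest comparison. Adjusted p-values are floored at 1e-300 rather
than reported as exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MergedMatrix

P_FLOOR = 1e-300
EPS = 1e-9


def differential_markers(
    merged: MergedMatrix,
    labels,
    test: str = "wilcoxon",
    use_corrected: bool = False,
) -> pd.DataFrame:
    """Per-gene cluster-vs-rest fold change and FDR-adjusted p-value.

    `labels` assigns each cell a cluster/family label. For each gene and
    label: ``fold_change = (mean expm1 in cluster + eps) / (mean expm1 in
    rest + eps)`` and a two-sided rank-sum (or Welch t) p-value on log
    values, BH-adjusted within each comparison. Returns a tidy frame with
    columns gene, cluster, fold_change, p_value, adjusted_p, direction.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != merged.n_cells:
        raise ValueError("label vector length != cell count")
    uniq = pd.unique(labels[labels != None])  # noqa: E711
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters for marker statistics")
    x = (
        merged.corrected
        if use_corrected
        else np.asarray(merged.values.todense())
    )  # genes x cells, log scale
    lin = np.expm1(x)
    frames = []
    for cl in uniq:
        in_c = labels == cl
        out_c = (labels != cl) & (labels != None)  # noqa: E711
        if in_c.sum() < 3 or out_c.sum() < 3:
            raise ValueError(f"cluster {cl!r} too small for marker statistics")
        mean_in = lin[:, in_c].mean(axis=1)
        mean_out = lin[:, out_c].mean(axis=1)
        fold = (mean_in + EPS) / (mean_out + EPS)
        if test == "wilcoxon":
            res = stats.mannwhitneyu(
                x[:, in_c], x[:, out_c], axis=1, alternative="two-sided"
            )
            pvals = res.pvalue
        elif test == "t":
            res = stats.ttest_ind(x[:, in_c], x[:, out_c], axis=1, equal_var=False)
            pvals = res.pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
        pvals = np.nan_to_num(pvals, nan=1.0)
        adj = multipletests(pvals, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "gene": merged.gene_names,
                    "cluster": cl,
                    "fold_change": fold,
                    "p_value": np.maximum(pvals, P_FLOOR),
                    "adjusted_p": np.maximum(adj, P_FLOOR),
                    "direction": np.where(fold >= 1, "up", "down"),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Identity assignment
# ---------------------------------------------------------------------------


def default_signatures() -> dict:
    """Characteristic-gene dictionary for the seven expected cell families."""
    path = resources.files("anlagen.data") / "signatures.tsv"
    table = pd.read_csv(path, sep="\t")
    return {
        row["identity"]: row["genes"].split(",") for _, row in table.iterrows()
    }


def assign_identity(stats_table: pd.DataFrame, signatures: dict = None) -> pd.DataFrame:
    """Score each cluster against each identity's signature genes.

    ``score(cluster, identity)`` is the mean ``-log10(adjusted_p)`` over the
    identity's signature genes that are upregulated (fold_change > 1) in the
    cluster; the argmax wins, ties broken by higher mean fold; a cluster with
    no upregulated signature gene is left unassigned.
    """
    if signatures is None:
        signatures = default_signatures()
    if not signatures:
        raise ValueError("empty signature table")
    rows = []
    for cl, sub in stats_table.groupby("cluster", sort=False):
        sub = sub.set_index("gene")
        best, best_score, best_fold = None, -np.inf, -np.inf
        for identity, genes in signatures.items():
            present = [g for g in genes if g in sub.index]
            up = [g for g in present if sub.loc[g, "fold_change"] > 1]
            if not up:
                continue
            score = float(np.mean(-np.log10(sub.loc[up, "adjusted_p"])))
            fold = float(np.mean(sub.loc[up, "fold_change"]))
            if score > best_score or (score == best_score and fold > best_fold):
                best, best_score, best_fold = identity, score, fold
        rows.append(
            (cl, best, best_score if best else np.nan, best is None)
        )
    return pd.DataFrame(rows, columns=["cluster", "identity", "score", "unassigned"])


# ---------------------------------------------------------------------------
# Timecourse log-fold-change heatmap
# ---------------------------------------------------------------------------


@dataclass
class TimecourseHeatmap:
    """log2 fold change vs day 0, genes x days, within one cluster."""

    values: pd.DataFrame  # index genes, columns days
    mask: pd.DataFrame  # True where the cluster is absent at that day
    cluster: object = None


def timecourse_lfc(
    merged: MergedMatrix,
    labels,
    cluster,
    genes: list,
    days: list = None,
    eps: float = EPS,
) -> TimecourseHeatmap:
    """Per-gene log2 fold change at each day vs day 0 within one cluster.

    ``entry(g, d) = log2((mean expm1 at day d + eps) / (mean expm1 at day 0 +
    eps))``; days where the cluster has no cells are masked. Raises KeyError
    naming any requested gene absent from the matrix.
    """
    labels = np.asarray(labels, dtype=object)
    gene_index = {g: i for i, g in enumerate(merged.gene_names)}
    missing = [g for g in genes if g not in gene_index]
    if missing:
        raise KeyError(f"gene(s) not in matrix: {missing}")
    days = sorted(set(merged.days)) if days is None else list(days)
    if 0 not in days or not ((labels == cluster) & (merged.days == 0)).any():
        raise ValueError(f"day 0 absent for cluster {cluster!r}")
    rows = np.array([gene_index[g] for g in genes])
    lin = np.expm1(np.asarray(merged.values[rows, :].todense()))
    in_cluster = labels == cluster
    base = lin[:, in_cluster & (merged.days == 0)].mean(axis=1)
    values = np.full((len(genes), len(days)), np.nan)
    mask = np.ones((len(genes), len(days)), bool)
    for j, d in enumerate(days):
        sel = in_cluster & (merged.days == d)
        if sel.any():
            mean_d = lin[:, sel].mean(axis=1)
            values[:, j] = np.log2((mean_d + eps) / (base + eps))
            mask[:, j] = False
    return TimecourseHeatmap(
        values=pd.DataFrame(values, index=list(genes), columns=days),
        mask=pd.DataFrame(mask, index=list(genes), columns=days),
        cluster=cluster,
    )
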