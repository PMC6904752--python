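"""Boolean marker gating of the mesenchymal family into subtypes.

Cells of the mesenchymal (MSC) family are stratified by marker positivity into
tenocytes (Scx+ Col1a1+), MSCs (Pdgfra+ Sox9- Runx2-), chondrocytes (Sox9+
Acan+ Col1a1+ Col3a1+) and preosteoblasts (Runx2+ Col1a1+). Positivity defaults
to raw UMI count > 0. The four rule sets are not mutually exclusive (Col1a1 is
shared), so overlaps are resolved by a deterministic priority order —
chondrocyte > preosteoblast > tenocyte > MSC by default — and cells matching no
rule are reported as unclassified, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNCLASSIFIED = "unclassified"


@dataclass
class GatingRule:
    """One subtype's boolean marker predicate.

    A cell is eligible iff every `positive` gene exceeds the positivity cutoff
    and no `negative` gene does. Lower `priority` wins among multiple
    eligible subtypes.
    """

    name: str
    positive: list
    negative: list = field(default_factory=list)
    priority: int = 99

    def __post_init__(self):
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(f"genes both required-positive and -negative: {sorted(overlap)}")


def default_gating_rules() -> list:
    """The four subtype rules with the default priority order."""
    path = resources.files("anlagen.data") / "gating_rules.tsv"
    table = pd.read_csv(path, sep="\t", keep_default_na=False)
    rules = []
    for _, row in table.iterrows():
        rules.append(
            GatingRule(
                name=row["subtype"],
                positive=[g for g in str(row["positive"]).split(",") if g],
                negative=[g for g in str(row["negative"]).split(",") if g],
                priority=int(row["priority"]),
            )
        )
    return rules


def gate_subtypes(
    counts,
    gene_names,
    rules: list = None,
    positivity_cutoff: float = 0.0,
) -> np.ndarray:
    """Assign each cell a subtype label (or ``"unclassified"``).

    `counts` is genes x cells (raw UMI counts); a gene is positive in a cell
    when its count strictly exceeds `positivity_cutoff`. Rules referencing a
    gene absent from `gene_names` raise KeyError.
    """
    rules = rules if rules is not None else default_gating_rules()
    gene_index = {g: i for i, g in enumerate(gene_names)}
    for rule in rules:
        missing = [g for g in rule.positive + rule.negative if g not in gene_index]
        if missing:
            raise KeyError(f"rule {rule.name!r} references absent gene(s): {missing}")
    x = sp.csr_matrix(counts)
    n_cells = x.shape[1]
    positive = {}  # gene -> boolean per cell
    needed = {g for r in rules for g in r.positive + r.negative}
    for g in needed:
        positive[g] = np.asarray(x[gene_index[g], :].todense()).ravel() > positivity_cutoff

    labels = np.full(n_cells, UNCLASSIFIED, dtype=object)
    best_priority = np.full(n_cells, np.inf)
    for rule in sorted(rules, key=lambda r: r.priority):
        eligible = np.ones(n_cells, bool)
        for g in rule.positive:
            eligible &= positive[g]
        for g in rule.negative:
            eligible &= ~positive[g]
        take = eligible & (rule.priority < best_priority)
        labels[take] = rule.name
        best_priority[take] = rule.priority
    return labels


def subtype_counts_and_profile(
    labels,
    counts,
    gene_names,
    days,
    target_gene: str = "Vegfa",
    positivity_cutoff: float = 0.0,
    scale_factor: float = 1e4,
):
    """Per-day subtype counts and a target-gene expression summary.

    Returns ``(counts_table, profile)``:

    * ``counts_table`` — integer day x subtype counts (plus unclassified);
      each row sums to the number of cells gated that day.
    * ``profile`` — per (subtype, day): number of cells, fraction with raw
      `target_gene` count above the positivity cutoff, and the median and
      mean log-normalised expression over all cells of the stratum.
    """
    labels = np.asarray(labels, dtype=object)
    days = np.asarray(days)
    x = sp.csr_matrix(counts)
    if len(labels) != x.shape[1] or len(days) != x.shape[1]:
        raise ValueError("labels/days length != cell count")
    gene_index = {g: i for i, g in enumerate(gene_names)}
    if target_gene not in gene_index:
        raise KeyError(f"target gene {target_gene!r} not in matrix")

    raw_target = np.asarray(x[gene_index[target_gene], :].todense()).ravel()
    totals = np.asarray(x.sum(axis=0)).ravel().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_expr = np.log1p(scale_factor * raw_target / np.maximum(totals, 1))

    subtype_order = [s for s in pd.unique(labels) if s != UNCLASSIFIED]
    columns = subtype_order + [UNCLASSIFIED]
    day_values = sorted(set(days.tolist()))
    counts_table = pd.DataFrame(0, index=day_values, columns=columns, dtype=int)
    rows = []
    for d in day_values:
        in_day = days == d
        for s in columns:
            sel = in_day & (labels == s)
            n = int(sel.sum())
            counts_table.loc[d, s] = n
            rows.append(
                {
                    "subtype": s,
                    "day": d,
                    "n_cells": n,
                    "fraction_expressing": float((raw_target[sel] > positivity_cutoff).mean()) if n else np.nan,
                    "median_log_expression": float(np.median(log_expr[sel])) if n else np.nan,
                    "mean_log_expression": float(np.mean(log_expr[sel])) if n else np.nan,
                }
            )
    profile = pd.DataFrame(rows)
    return counts_table, profile
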