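"""Hierarchical cytometry gating and group comparison.

The gate tree reproduces the study's endothelial-progenitor analysis: after
excluding nonviable events (high viability-dye signal), the CD31- Tie2-
double-negative population refined for CD34+ CD133+ defines endothelial
progenitor cells (EPC); the CD31+ Tie2+ double-positive population refined for
CD133- CD34- defines mature endothelium; everything else viable is other-live.
Event counts are normalised to total viable cells per sample, and
injured-vs-contralateral comparisons report the fold change, Levene and F
variance tests, and a pooled-variance Student's t (with the Welch variant
reported alongside when the F-test rejects homoscedasticity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_CHANNELS = ["Tie2", "CD31", "CD133", "CD34", "viability"]

EPC = "EPC"
ENDO = "endothelium"
OTHER = "other_live"
NONVIABLE = "nonviable"


@dataclass
class GateTree:
    """Per-channel positivity cutoffs for the fixed gate hierarchy.

    An event is viable when its viability-dye intensity is at or below
    ``viability_cutoff`` (the dye marks dead cells). A surface channel is
    positive when strictly above its cutoff.
    """

    cutoffs: dict = field(
        default_factory=lambda: {"Tie2": 500.0, "CD31": 500.0, "CD133": 500.0, "CD34": 500.0}
    )
    viability_cutoff: float = 1000.0


def gate_events(events: pd.DataFrame, tree: GateTree = None) -> pd.DataFrame:
    """Label every event EPC / endothelium / other_live / nonviable.

    `events` must carry the four surface channels plus ``viability``; any
    other columns (sample id, group, truth labels) pass through unchanged.
    Returns a copy with a ``label`` column.
    """
    tree = tree or GateTree()
    missing = [c for c in REQUIRED_CHANNELS if c not in events.columns]
    if missing:
        raise KeyError(f"missing channel column(s): {missing}")
    out = events.copy()
    viable = out["viability"].to_numpy() <= tree.viability_cutoff
    pos = {ch: out[ch].to_numpy() > tree.cutoffs[ch] for ch in tree.cutoffs}
    is_epc = ~pos["CD31"] & ~pos["Tie2"] & pos["CD34"] & pos["CD133"]
    is_endo = pos["CD31"] & pos["Tie2"] & ~pos["CD133"] & ~pos["CD34"]
    label = np.where(
        ~viable, NONVIABLE, np.where(is_epc, EPC, np.where(is_endo, ENDO, OTHER))
    )
    out["label"] = label
    return out


def population_counts(gated: pd.DataFrame, sample_col: str = "sample_id") -> pd.DataFrame:
    """Per-sample counts of each population and of total viable events."""
    if sample_col not in gated.columns:
        raise KeyError(f"no {sample_col!r} column")
    rows = []
    for sid, sub in gated.groupby(sample_col, sort=False):
        viable = sub[sub["label"] != NONVIABLE]
        if len(viable) == 0:
            raise ValueError(f"sample {sid!r} has zero viable events")
        rows.append(
            {
                sample_col: sid,
                EPC: int((viable["label"] == EPC).sum()),
                ENDO: int((viable["label"] == ENDO).sum()),
                OTHER: int((viable["label"] == OTHER).sum()),
                "viable": len(viable),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Injured-vs-contralateral comparison of one population's frequencies."""

    population: str
    frequencies: pd.DataFrame  # sample, group, frequency
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    fold_change: float
    levene_p: float
    f_test_p: float
    t_statistic: float
    t_p: float
    welch_statistic: float
    welch_p: float
    homoscedastic: bool

    def summary(self) -> str:
        return (
            f"{self.population}: fold change {self.fold_change:.3f} "
            f"({self.mean_a:.4g} vs {self.mean_b:.4g}); "
            f"Levene p={self.levene_p:.3g}, F-test p={self.f_test_p:.3g}; "
            f"Student t={self.t_statistic:.3f} p={self.t_p:.3g}"
            + ("" if self.homoscedastic else f"; Welch t={self.welch_statistic:.3f} p={self.welch_p:.3g} (F-test rejected)")
        )


def _f_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-test for equal variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    f = va / vb if vb > 0 else np.inf
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    return float(min(p, 1.0))


def compare_groups(
    counts: pd.DataFrame,
    population: str,
    groups: dict,
    group_a: str = "injured",
    group_b: str = "contralateral",
    alpha: float = 0.05,
    sample_col: str = "sample_id",
) -> GroupComparison:
    """Compare per-sample frequencies of `population` between two groups.

    `counts` is the output of :func:`population_counts`; `groups` maps sample
    id to group name. Frequency = population count / viable count. The fold
    change is ``mean(group_a) / mean(group_b)``.
    """
    freq = counts.copy()
    freq["group"] = freq[sample_col].map(groups)
    freq["frequency"] = freq[population] / freq["viable"]
    a = freq.loc[freq["group"] == group_a, "frequency"].to_numpy(float)
    b = freq.loc[freq["group"] == group_b, "frequency"].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    mean_a, mean_b = a.mean(), b.mean()
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and mean_a == mean_b:
        levene_p = 1.0
    else:
        levene_p = float(stats.levene(a, b).pvalue)
    f_p = _f_test(a, b)
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and mean_a == mean_b:
        t_stat, t_p = 0.0, 1.0
        w_stat, w_p = 0.0, 1.0
    else:
        t_res = stats.ttest_ind(a, b, equal_var=True)
        w_res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, t_p = float(t_res.statistic), float(t_res.pvalue)
        w_stat, w_p = float(w_res.statistic), float(w_res.pvalue)
    return GroupComparison(
        population=population,
        frequencies=freq[[sample_col, "group", "frequency"]],
        mean_a=mean_a,
        mean_b=mean_b,
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        fold_change=mean_a / mean_b if mean_b > 0 else np.inf,
        levene_p=levene_p,
        f_test_p=f_p,
        t_statistic=t_stat,
        t_p=t_p,
        welch_statistic=w_stat,
        welch_p=w_p,
        homoscedastic=f_p >= alpha,
    )
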