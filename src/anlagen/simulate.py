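"""Synthetic inputs with known ground truth.

The generator emulates the structure of the timecourse experiment the pipeline
analyses: four timepoints (days 0, 3, 7, 21 post injury), two replicates per
timepoint, a few hundred cells per replicate, and seven cell families each
carrying a block of characteristic marker genes (the real marker names of the
study system — Pdgfra/Prrx1, Pax7, Plp1/Cnp/Dhh, Acta2/Mylk, Cdh5/Pecam1/Cd34,
Ms4a1, Ccr2/... — padded with synthetic markers to a configurable block size).
The mesenchymal family carries a differentiation continuum of four subtypes
(tenocyte, MSC, chondrocyte, preosteoblast) defined by the boolean marker
programs used downstream for gating, with per-day mixing weights and a
programmable Vegfa mean per (subtype, day).

Counts follow a negative-binomial law with a log-normal per-cell depth;
replicate batch effects are multiplicative log-normal gene factors; a designated
set of genes is named with the mouse mitochondrial prefix ``mt-`` so QC is
exercisable. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix

# Mouse mitochondrial protein-coding genes; used to name the mito block.
MITO_GENES = [
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
]

# Genes used by the subtype gating programs; kept at a very low baseline in
# every cell so that positivity (raw count > 0) is informative.
GATING_GENES = ["Scx", "Col1a1", "Sox9", "Acan", "Col3a1", "Runx2", "Vegfa"]


@dataclass
class SubtypeSpec:
    """One subtype of the mesenchymal continuum.

    ``program`` lists the gating genes this subtype switches on;
    ``weights`` maps day -> mixing proportion (summing to 1 per day across the
    family's subtypes); ``vegfa_fold`` maps day -> fold elevation of Vegfa
    relative to its baseline.
    """

    name: str
    program: list
    weights: dict
    vegfa_fold: dict = field(default_factory=dict)
    program_fold: float = 40.0


@dataclass
class FamilySpec:
    """A cell family and its marker block.

    ``marker_genes`` are elevated ``marker_fold``-fold over their baseline in
    cells of this family. Marker lists must be disjoint between families.
    """

    name: str
    marker_genes: list
    marker_fold: float = 5.0
    subtypes: list = None

    def __post_init__(self):
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")
        if not self.marker_genes:
            raise ValueError(f"family {self.name!r} has no marker genes")


@dataclass
class SimConfig:
    """Full specification of a synthetic timecourse.

    ``composition`` maps day -> {family name: proportion}; proportions must sum
    to 1 within each day. ``depth_mean``/``depth_dispersion`` set the mean and
    coefficient of variation of the log-normal per-cell total UMI count;
    ``nb_dispersion`` is the gene-level negative-binomial dispersion (variance
    = mu + dispersion * mu^2). ``batch_effect_sd`` is the SD of the log-scale
    multiplicative per-replicate gene factor. The seed fully determines output.
    """

    n_genes: int = 1000
    families: list = None
    timepoints: list = field(default_factory=lambda: [0, 3, 7, 21])
    replicates_per_timepoint: int = 2
    cells_per_replicate: int = 500
    composition: dict = None
    depth_mean: float = 3000.0
    depth_dispersion: float = 0.3
    nb_dispersion: float = 0.15
    batch_effect_sd: float = 0.1
    mito_fraction_range: tuple = (0.02, 0.08)
    noise_free: bool = False
    allow_shared_markers: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.families is None:
            self.families = default_families()
        if self.composition is None:
            self.composition = default_composition([f.name for f in self.families], self.timepoints)
        self.validate()

    def validate(self):
        if self.n_genes <= 0 or self.cells_per_replicate <= 0 or self.replicates_per_timepoint <= 0:
            raise ValueError("counts and dimensions must be positive")
        if not self.families:
            raise ValueError("at least one family required")
        names = [f.name for f in self.families]
        if len(set(names)) != len(names):
            raise ValueError("duplicate family names")
        if not self.allow_shared_markers:
            seen = set()
            for f in self.families:
                overlap = seen & set(f.marker_genes)
                if overlap:
                    raise ValueError(f"marker genes shared between families: {sorted(overlap)}")
                seen |= set(f.marker_genes)
        for day in self.timepoints:
            props = self.composition.get(day)
            if props is None:
                raise ValueError(f"no composition for day {day}")
            total = sum(props.get(n, 0.0) for n in names)
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"composition for day {day} sums to {total}, not 1")
            if any(p < 0 for p in props.values()):
                raise ValueError("negative composition proportion")
        for f in self.families:
            if f.subtypes:
                for day in self.timepoints:
                    w = sum(s.weights.get(day, 0.0) for s in f.subtypes)
                    if abs(w - 1.0) > 1e-8:
                        raise ValueError(
                            f"subtype weights of family {f.name!r} sum to {w} on day {day}"
                        )
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("mito_fraction_range must lie within [0, 1]")


@dataclass
class GroundTruth:
    """Per-cell and per-gene generative labels for a simulated timecourse."""

    cells: pd.DataFrame  # barcode, replicate, day, family, subtype
    genes: pd.DataFrame  # gene, family (marker-of, or NA), fold


def default_subtypes() -> list:
    """The mesenchymal differentiation continuum with its gating programs.

    Day-7 weights approximate the dominant-MSC mixture the study design
    expects (roughly half MSC, with preosteoblasts the next largest group);
    Vegfa dynamics encode: low tenocyte signal attenuated by day 7, an MSC
    and chondrocyte peak at day 3 dissipating by day 7, and a sustained
    preosteoblast signal through day 21.
    """
    return [
        SubtypeSpec(
            "tenocyte",
            ["Scx", "Col1a1"],
            weights={0: 0.30, 3: 0.12, 7: 0.12, 21: 0.08},
            vegfa_fold={0: 3, 3: 2, 7: 1, 21: 1},
        ),
        SubtypeSpec(
            "MSC",
            [],  # defined by family marker Pdgfra and absence of Sox9/Runx2
            weights={0: 0.60, 3: 0.70, 7: 0.48, 21: 0.35},
            vegfa_fold={0: 1, 3: 8, 7: 2, 21: 1},
        ),
        SubtypeSpec(
            "chondrocyte",
            ["Sox9", "Acan", "Col1a1", "Col3a1"],
            weights={0: 0.03, 3: 0.08, 7: 0.10, 21: 0.12},
            vegfa_fold={0: 1, 3: 6, 7: 2, 21: 1},
        ),
        SubtypeSpec(
            "preosteoblast",
            ["Runx2", "Col1a1"],
            weights={0: 0.07, 3: 0.10, 7: 0.30, 21: 0.45},
            vegfa_fold={0: 1, 3: 4, 7: 4, 21: 4},
        ),
    ]


def default_families(marker_fold: float = 5.0, markers_per_family: int = 20) -> list:
    """Seven families mirroring the study's cluster identities.

    Each family's characteristic genes are padded with synthetic markers
    (``<Name>mk03`` ...) to `markers_per_family`, so the family signal spans a
    block of genes rather than a handful.
    """
    seeds = {
        "Mesenchymal": ["Pdgfra", "Prrx1", "Osr2", "En1"],
        "Satellite": ["Pax7"],
        "Schwann": ["Plp1", "Cnp", "Dhh"],
        "Myofibroblast": ["Acta2", "Mylk"],
        "Endothelial": ["Cdh5", "Pecam1", "Cd34", "Prom1"],
        "Lymphocyte": ["Ms4a1"],
        "Myeloid": ["Ccr2", "Mrc1", "Fcgr1", "Ccr1", "S100a9", "Cd209a"],
    }
    families = []
    for name, markers in seeds.items():
        markers = list(markers)
        i = len(markers)
        while len(markers) < markers_per_family:
            i += 1
            markers.append(f"{name}mk{i:02d}")
        subtypes = default_subtypes() if name == "Mesenchymal" else None
        families.append(FamilySpec(name, markers, marker_fold=marker_fold, subtypes=subtypes))
    return families


def default_composition(names: list, timepoints: list) -> dict:
    """Timepoint-dependent family proportions.

    Day 0 is the uninjured steady state; the inflammatory (myeloid) fraction
    expands after injury while the mesenchymal family peaks around day 7.
    Families never drop below ~7% so each is present in every replicate.
    """
    base = {
        0: [0.28, 0.15, 0.10, 0.10, 0.10, 0.11, 0.16],
        3: [0.24, 0.10, 0.08, 0.10, 0.12, 0.10, 0.26],
        7: [0.33, 0.08, 0.07, 0.10, 0.12, 0.09, 0.21],
        21: [0.30, 0.10, 0.09, 0.12, 0.13, 0.10, 0.16],
    }
    if len(names) == 7:
        table = {d: dict(zip(names, base[d] if d in base else base[0])) for d in timepoints}
    else:
        # uniform fallback for non-default family sets
        table = {d: {n: 1.0 / len(names) for n in names} for d in timepoints}
        for d in timepoints:
            # fix rounding so proportions sum exactly to 1
            total = sum(table[d].values())
            table[d][names[0]] += 1.0 - total
    return table


def default_config(**overrides) -> SimConfig:
    """The default study-design scenario (7 families, 4 days x 2 replicates)."""
    return SimConfig(**overrides)


def _gene_table(config: SimConfig, rng: np.random.Generator):
    """Build the gene list and per-(family, subtype, day) relative-expression programs."""
    marker_genes = list(
        dict.fromkeys(g for f in config.families for g in f.marker_genes)
    )
    special = set(marker_genes) | set(GATING_GENES) | set(MITO_GENES)
    n_special = len(MITO_GENES) + len(marker_genes) + len(GATING_GENES)
    n_background = config.n_genes - n_special
    if n_background < 0:
        raise ValueError(
            f"n_genes={config.n_genes} too small for {n_special} named genes"
        )
    background = [f"Gene{i:05d}" for i in range(n_background)]
    genes = MITO_GENES + marker_genes + GATING_GENES + background
    assert len(genes) == config.n_genes

    # Baseline relative expression, shared by every sample so that family
    # centroids are comparable across replicates.
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    # marker genes get a baseline floor so a family's markers are never
    # near-silent (their fold elevation must be observable)
    for g in marker_genes:
        base[gene_index[g]] = max(base[gene_index[g]], 0.5)
    for g in GATING_GENES:
        base[gene_index[g]] = 0.02  # near-silent unless a program switches it on
    return genes, gene_index, base


def _program_expression(base, gene_index, family: FamilySpec, subtype, day):
    """Relative expression vector for cells of (family, subtype) at `day`."""
    rel = base.copy()
    for g in family.marker_genes:
        rel[gene_index[g]] *= family.marker_fold
    if subtype is not None:
        for g in subtype.program:
            rel[gene_index[g]] *= subtype.program_fold
        fold = subtype.vegfa_fold.get(day, 1.0)
        rel[gene_index["Vegfa"]] *= fold * subtype.program_fold / 4.0
    return rel


def _sample_counts(rng, mu, dispersion, noise_free):
    if noise_free:
        return np.round(mu).astype(np.int64)
    if dispersion <= 0:
        return rng.poisson(mu).astype(np.int64)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p).astype(np.int64)


def simulate_timecourse(config: SimConfig):
    """Generate one :class:`CountMatrix` per (timepoint, replicate) plus truth.

    Returns ``(matrices, truth)`` where `matrices` is a list ordered by
    (day, replicate) and `truth` is a :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, gene_index, base = _gene_table(config, rng)
    mito_idx = np.array([gene_index[g] for g in MITO_GENES])
    mito_mask = np.zeros(config.n_genes, bool)
    mito_mask[mito_idx] = True

    fam_by_name = {f.name: f for f in config.families}
    fam_names = [f.name for f in config.families]

    matrices = []
    cell_rows = []
    for day in config.timepoints:
        props = np.array([config.composition[day][n] for n in fam_names])
        for r in range(1, config.replicates_per_timepoint + 1):
            replicate = f"r{r}"
            n_cells = config.cells_per_replicate
            # replicate batch effect: multiplicative log-normal gene factor
            if config.batch_effect_sd > 0 and not config.noise_free:
                batch_factor = rng.lognormal(0.0, config.batch_effect_sd, size=config.n_genes)
            else:
                batch_factor = np.ones(config.n_genes)

            if config.noise_free:
                fam_labels = np.repeat(
                    np.arange(len(fam_names)), np.round(props * n_cells).astype(int)
                )[:n_cells]
                if len(fam_labels) < n_cells:
                    fam_labels = np.concatenate(
                        [fam_labels, np.full(n_cells - len(fam_labels), int(np.argmax(props)))]
                    )
            else:
                fam_labels = rng.choice(len(fam_names), size=n_cells, p=props)

            if config.noise_free:
                depths = np.full(n_cells, config.depth_mean)
                mito_frac = np.full(n_cells, float(np.mean(config.mito_fraction_range)))
            else:
                sigma = np.sqrt(np.log1p(config.depth_dispersion**2))
                mu_log = np.log(config.depth_mean) - sigma**2 / 2.0
                depths = rng.lognormal(mu_log, sigma, size=n_cells)
                lo, hi = config.mito_fraction_range
                mito_frac = rng.uniform(lo, hi, size=n_cells)

            subtype_labels = np.array([""] * n_cells, dtype=object)
            counts = np.zeros((n_cells, config.n_genes), dtype=np.int64)
            for fi, fname in enumerate(fam_names):
                fam = fam_by_name[fname]
                idx = np.flatnonzero(fam_labels == fi)
                if idx.size == 0:
                    continue
                if fam.subtypes:
                    w = np.array([s.weights.get(day, 0.0) for s in fam.subtypes])
                    w = w / w.sum()
                    if config.noise_free:
                        sub_assign = np.repeat(
                            np.arange(len(fam.subtypes)), np.round(w * idx.size).astype(int)
                        )[: idx.size]
                        if len(sub_assign) < idx.size:
                            sub_assign = np.concatenate(
                                [sub_assign, np.full(idx.size - len(sub_assign), int(np.argmax(w)))]
                            )
                    else:
                        sub_assign = rng.choice(len(fam.subtypes), size=idx.size, p=w)
                    groups = [(fam.subtypes[si], idx[sub_assign == si]) for si in range(len(fam.subtypes))]
                else:
                    groups = [(None, idx)]
                for subtype, gidx in groups:
                    if gidx.size == 0:
                        continue
                    rel = _program_expression(base, gene_index, fam, subtype, day)
                    rel = rel * batch_factor
                    # split probability mass between mito and nuclear genes per cell
                    p_mito = rel[mito_mask] / rel[mito_mask].sum()
                    p_nuc = rel[~mito_mask] / rel[~mito_mask].sum()
                    f = mito_frac[gidx][:, None]
                    p = np.empty((gidx.size, config.n_genes))
                    p[:, mito_mask] = f * p_mito[None, :]
                    p[:, ~mito_mask] = (1 - f) * p_nuc[None, :]
                    mu = depths[gidx][:, None] * p
                    counts[gidx, :] = _sample_counts(rng, mu, config.nb_dispersion, config.noise_free)
                    if subtype is not None:
                        subtype_labels[gidx] = subtype.name

            barcodes = np.array(
                [f"d{day}-{replicate}-c{i:05d}" for i in range(n_cells)], dtype=object
            )
            matrices.append(
                CountMatrix(
                    sp.csr_matrix(counts.T),
                    np.asarray(genes, dtype=object),
                    barcodes,
                    replicate=replicate,
                    day=day,
                )
            )
            for i in range(n_cells):
                cell_rows.append(
                    (
                        barcodes[i],
                        replicate,
                        day,
                        fam_names[fam_labels[i]],
                        subtype_labels[i] or None,
                    )
                )

    gene_rows = []
    marker_of = {}
    for f in config.families:
        for g in f.marker_genes:
            marker_of[g] = (f.name, f.marker_fold)
    for g in genes:
        fam, fold = marker_of.get(g, (None, 1.0))
        gene_rows.append((g, fam, fold))
    truth = GroundTruth(
        cells=pd.DataFrame(cell_rows, columns=["barcode", "replicate", "day", "family", "subtype"]),
        genes=pd.DataFrame(gene_rows, columns=["gene", "family", "fold"]),
    )
    return matrices, truth


# ---------------------------------------------------------------------------
# Cytometry events
# ---------------------------------------------------------------------------

CYTO_CHANNELS = ["Tie2", "CD31", "CD133", "CD34", "viability"]

#: default per-population channel means/sds; negative channels sit well below,
#: positive well above, the default gate cutoff of 500. Viability is a
#: dead-cell dye (propidium-iodide-like): live events are LOW.
DEFAULT_CHANNEL_PARAMS = {
    "EPC": {"Tie2": (100, 30), "CD31": (100, 30), "CD133": (1200, 200), "CD34": (1200, 200), "viability": (80, 25)},
    "endothelium": {"Tie2": (1200, 200), "CD31": (1200, 200), "CD133": (100, 30), "CD34": (100, 30), "viability": (80, 25)},
    "other": {"Tie2": (150, 60), "CD31": (150, 60), "CD133": (150, 60), "CD34": (150, 60), "viability": (80, 25)},
    "dead": {"Tie2": (150, 60), "CD31": (150, 60), "CD133": (150, 60), "CD34": (150, 60), "viability": (4000, 600)},
}


def simulate_cytometry(
    n_events: int,
    population_fractions: dict,
    channel_params: dict = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a cytometry event table with ground-truth population labels.

    ``population_fractions`` maps population name (e.g. ``"EPC"``,
    ``"endothelium"``, ``"dead"``) to its fraction of events; fractions must
    sum to at most 1 and the remainder becomes ``"other"`` live cells.
    Channel intensities are Gaussian per population with the means/sds of
    `channel_params` (defaults above). Deterministic given `seed`.
    """
    fractions = dict(population_fractions)
    total = sum(fractions.values())
    if total > 1 + 1e-9:
        raise ValueError(f"population fractions sum to {total} > 1")
    if any(v < 0 for v in fractions.values()):
        raise ValueError("negative population fraction")
    fractions["other"] = fractions.get("other", 0.0) + (1.0 - min(total, 1.0))
    params = dict(DEFAULT_CHANNEL_PARAMS)
    if channel_params:
        for pop, chans in channel_params.items():
            params[pop] = {**params.get(pop, params["other"]), **chans}

    rng = np.random.default_rng(seed)
    pops = sorted(fractions)
    probs = np.array([fractions[p] for p in pops])
    probs = probs / probs.sum()
    labels = rng.choice(len(pops), size=n_events, p=probs)
    data = {"population": [pops[i] for i in labels]}
    for ch in CYTO_CHANNELS:
        means = np.array([params[p][ch][0] for p in pops])
        sds = np.array([params[p][ch][1] for p in pops])
        data[ch] = np.maximum(rng.normal(means[labels], sds[labels]), 0.0)
    df = pd.DataFrame(data)
    return df[CYTO_CHANNELS + ["population"]]


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def simulate_image(
    shape,
    foreground_fraction: float,
    fg_mean: float,
    bg_mean: float,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Bimodal intensity image with a recorded true foreground mask.

    Exactly ``round(foreground_fraction * n_pixels)`` pixels take the
    foreground mean (plus Gaussian noise, clipped at zero); the rest take the
    background mean. Returns ``(image, mask)``.
    """
    if fg_mean <= bg_mean:
        raise ValueError("fg_mean must exceed bg_mean")
    if not 0 <= foreground_fraction <= 1:
        raise ValueError("foreground_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(np.prod(shape))
    n_fg = int(round(foreground_fraction * n))
    mask = np.zeros(n, bool)
    mask[rng.choice(n, size=n_fg, replace=False)] = True
    image = np.where(mask, float(fg_mean), float(bg_mean))
    if noise_sd > 0:
        image = np.maximum(image + rng.normal(0.0, noise_sd, size=n), 0.0)
    return image.reshape(shape), mask.reshape(shape)
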