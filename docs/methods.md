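# Methods

## Scope and design

The package reimplements, as a tested pipeline on synthetic data, the
downstream analysis of a timecourse single-cell RNA-seq experiment in a
trauma-induced heterotopic-ossification model, together with its ancillary
quantifications (cytometry gate statistics, Yen image thresholding, microCT
volumetry). The deposited animal data themselves are not reproducible at desk
scale — the original clustering algorithm, resolution and alignment threshold
are unpublished, and the flow/CT endpoints come from live animals — so the
package's claims are *property-based*: every stage is exercised against a
generator with known ground truth, and the quantities reported by
`scripts/acceptance.py` are recoveries of planted structure, not re-derivations
of animal results.

## The consolidation model

Cells from each replicate are treated as draws from a mixture of cell
families; a family is considered real when its provisional cluster reappears
across replicates. Concretely:

- **QC.** Cell filters use strict inequalities ("fewer than 500 genes",
  "more than 10%", "more than 60 000 UMIs" — equality retains); the gene
  filter (expressed in < 10 surviving cells) can push cells back below the
  gene threshold, so the two filters are iterated to a fixed point, which
  also makes the result independent of filter order. Mitochondrial content is
  computed over UMIs from `mt-`-prefixed genes (mouse nomenclature).
- **Normalisation.** `ln(1 + 10⁴·c/total)`, natural log. The inverse
  transform recovers the scale factor exactly per cell (tested at 1e-8
  relative error); log2 is reserved for reported fold changes.
- **HVG/PCA.** Highly variable genes are the top 2000 by plain log-space
  variance — a deliberately simple, deterministic criterion. For
  cross-replicate comparability a single shared HVG set is computed on the
  gene intersection using summed per-replicate variances. Genes are z-scored
  with clipping at |z| = 10; the PCA sign convention (largest-magnitude
  loading positive) makes embeddings reproducible.
- **Provisional clustering.** Two interchangeable backends: k-means with
  fixed k (default, deterministic given seed, used throughout the tests) and
  Leiden at a resolution parameter on a kNN graph. Cluster ids are relabelled
  by decreasing size.
- **Rank correlation.** "Rank correlated by centroids" is operationalised as
  Spearman with average ranks between per-cluster mean log-normalised HVG
  vectors, computed within each replicate *before* batch correction
  (replicate-local comparison precedes merging in the procedure's order).
  Zero-variance centroids yield NaN with a warning rather than a silent 0.
- **Matching and discard.** Reciprocal best correlation with ρ ≥ 0.5 is the
  default alignment criterion (the threshold is a configuration choice — no
  numeric criterion is published for "failed to align"); a Hungarian
  assignment backend is available for sensitivity analysis and agrees with
  reciprocal-best on clean fixtures. A provisional cluster must align in all
  of its within-timepoint comparisons (configurable fraction) or it is
  discarded along with its cells.
- **Families.** Connected components of the match graph over retained
  clusters, across replicates and timepoints, named A, B, C… by decreasing
  total cell count. A component containing two clusters of the same sample is
  contradictory; it is reduced to its maximum spanning tree (strongest edges
  kept) and, for each conflicting pair, the weakest edge on the tree path
  between them is cut — a single-linkage-style split that preserves the
  strongest backbone instead of shredding the component.
- **Batch correction.** Per-gene batch-mean centring to the pooled gene mean.
  This removes exactly the additive (log-scale) replicate offsets the
  generator plants and keeps the procedure deterministic and invertible;
  nothing fancier is attempted, and corrected values are stored alongside the
  originals. Batches with < 2 cells are excluded with a warning.
- **Final clustering.** k-means (k = number of families found, overridable)
  on PCA of the corrected merged matrix; each final cluster inherits the
  family with which it shares a plurality of cells, and a per-(day,
  replicate) contribution table is emitted.

**Diagnostics.** `diagonal_dominance` is the fraction of matched clusters
whose partner is the strict row maximum of the correlation map — 1.0 is the
"red diagonal" of a stability heatmap — and the per-row off-match maximum is
reported to surface secondary affinities (two families sharing part of a
transcriptional program show elevated mutual off-diagonal ρ; the generator can
plant this and the package's tests confirm the signature).

## Marker statistics and identities

Cluster-vs-rest fold change is `(mean expm1 + ε)/(mean expm1 rest + ε)` with
ε = 1e-9 on the ratio scale (matching the convention in which published
characteristic-gene tables report ratios like 22.6, not logs). P-values come
from the two-sided Wilcoxon rank-sum test on log values (config-switchable to
Welch's t), BH-adjusted within each cluster comparison, floored at 1e-300
instead of reporting exact zeros. Identity scores are the mean
−log10(adjusted p) of a signature's genes restricted to genes upregulated in
the cluster; ties break by higher mean fold; a cluster with no upregulated
signature gene stays unassigned. Timecourse heatmaps report
`log2((mean expm1 at day d + ε)/(mean expm1 at day 0 + ε))` within a cluster,
masking days where the cluster is absent.

## Subtype gating

Positivity defaults to raw UMI count > 0 — the minimal reading of the +/−
superscripts in the gating rules (a normalised-value cutoff is available).
The four rule sets overlap (Col1a1 is shared; Sox9/Runx2 co-positivity
occurs), so a deterministic priority resolves multiple eligibility:
chondrocyte > preosteoblast > tenocyte > MSC, exposed in the rules table.
Unclassified cells are counted, never dropped, so the counts table always
partitions its input.

## Cytometry

The gate tree takes per-channel cutoffs as configuration (gating is an
operator choice; no compensation or spillover modelling). The viability
channel is a dead-cell dye: live means *at or below* the cutoff. Frequencies
are population counts over viable events per sample. Group comparisons report
the mean-ratio fold change, Levene's test and the two-sided F-test for
homoscedasticity, and a pooled-variance Student's t; when the F-test rejects
at 0.05 the Welch statistic is reported alongside rather than silently
substituted. Input is plain CSV event tables; an FCS adapter is an extension
point, not a dependency.

## Imaging

Yen's threshold maximises the entropic-correlation criterion
`TC(t) = −ln(G1·G2/(P²(1−P)²))` on a 256-bin histogram; ties break toward the
lower threshold, and the threshold bin belongs to the background (positive
means strictly above). The implementation is checked against an independent
exhaustive-split oracle and cross-checked against scikit-image's Yen filter
(agreement within bin width). CT volumes count voxels at or *at least* the HU
threshold ("threshold of 800" read as minimum included density) times the
voxel volume; region-of-interest delineation is a user-supplied mask, since
anatomical landmarking is manual.

## The synthetic-data generator

Counts are negative binomial with gene-level dispersion 0.15 (variance
μ + 0.15μ²) and a log-normal per-cell depth (mean 3000 UMIs, CV 0.3) — a
standard overdispersed scRNA-seq model. The default design mirrors the study
structure: days 0/3/7/21, two replicates per timepoint (a choice — replicate
counts are not published), 500 cells per replicate, seven families whose
marker blocks carry the real characteristic genes padded with synthetic
markers to 20 per family at fold 5 over a log-normal baseline (marker
baselines floored at 0.5 so a family's markers are never near-silent).
Replicate batch effects are multiplicative log-normal gene factors (σ = 0.1),
the simplest structure that makes mean-centring correction testable.
Mitochondrial genes use the 13 mouse `mt-` protein genes with per-cell mito
fraction uniform on [0.02, 0.08]. Composition varies by day (myeloid expands
after injury, mesenchymal peaks near day 7; every family stays above ~7% so
each is present in every replicate). The mesenchymal family carries four
subtypes defined by the same boolean marker programs the gating module uses,
with day-dependent weights and Vegfa fold profiles encoding: low tenocyte
signal attenuated by day 7, an MSC/chondrocyte peak at day 3 dissipating by
day 7, and a sustained preosteoblast signal through day 21. A `noise_free`
mode replaces sampling with rounded expected counts for exactness tests.

What the generator does **not** emulate: doublets, ambient RNA, read-level
structure, nonlinear batch effects, continuous differentiation trajectories
(subtypes are discrete), or realistic gene–gene correlation beyond the
planted programs. Passing tests therefore demonstrate correctness of the
procedures under the stated generative model, not performance on real tissue.

## Problem sizes and numerical choices

Tests and the acceptance script use 4 × 2 samples at 200–500 cells and
500–1000 genes, 20-seed replications for stochastic properties, 50 random
images for the Yen oracle and 20 random volumes for CT monotonicity — sizes
at which every targeted property is already sharply testable. Spearman
comparisons use average ranks and are clipped to [−1, 1]; PCA uses the full
SVD solver for determinism; k-means uses 10 restarts with a fixed seed.

## Known limitations

- Reciprocal-best matching is greedy; pathological correlation maps can
  leave legitimately matched clusters unmatched (the Hungarian backend is
  provided for such cases).
- The discard rule treats all within-timepoint comparisons equally; with
  many replicates a fractional requirement may be preferable to "all".
- Batch-mean centring cannot remove batch effects that interact with cell
  type (it matches the generator's additive model by construction).
- Family letters are data-ordered (by cell count); they are not comparable
  across runs with different compositions.
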