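# Methods

## Contraction quantification

A video is an ordered stack of grayscale frames `I(t, x, y)` with
intensities normalized to [0, 1] on read (8-bit ÷ 255, 16-bit ÷ 65535, RGB
reduced to BT.601 luminance), which keeps scores comparable across bit
depths and containers.  The change-heat map is the mean absolute
difference between frames a fixed lag apart,

    heat(x, y) = (1 / (T − ℓ)) · Σ_{t=0}^{T−ℓ−1} |I(t+ℓ, x, y) − I(t, x, y)|,

with ℓ = 4 frames by default.  "Every 4 frames" is read as a *sliding*
lag — every pair (t, t+ℓ) contributes — rather than disjoint 4-frame
blocks: sliding uses all of the video and the disjoint variant is a strict
subsample of it.  The disjoint variant and a squared-difference variant
remain available behind flags for sensitivity studies.  Absolute (not
signed, not squared) differences are the default because the statistic
quantifies the magnitude of gray change.

The scalar contraction score is the unweighted spatial mean of the heat
map, over the whole frame by default or over a user-supplied mask; the
whole-frame mean is the least arbitrary reduction when no region of
interest is defined.  No background subtraction is applied by default.

Two numerical choices make the statistic exactly reproducible: per pixel,
the differences are accumulated in ascending order (a canonical order, so
reversing the frame sequence gives a bit-identical heat map), and the
spatial mean uses exactly rounded summation (`math.fsum`), so the score is
invariant to pixel ordering.  Both properties are asserted bit-exactly in
tests, as is equality with a naive double-loop reference implementation.

Useful consequences, also under test: heat lies in [0, 1] for inputs in
[0, 1]; scaling all intensities by a factor scales heat and score by
exactly that factor; a static noise-free video scores exactly 0.

Group comparison is a one-way ANOVA (scipy) across groups of per-organoid
scores, reported with per-group mean/sd and star codes (* p<0.05,
** p<0.01, *** p<0.001).

## Single-cell pipeline

Stage order is gene filter → cell filter → log-normalization, with cell
totals computed on the filtered matrix; this makes the per-cell identity
`Σ_genes (exp(value) − 1) = scale factor` hold exactly (asserted to 1e-8).

* **Gene filter**: keep genes with a count strictly greater than 1 in at
  least 3 cells.  The strict reading ("greater than 1") is deliberate; a
  `min_count` parameter relaxes it.
* **Cell filter**: keep cells expressing (count > 0) at least `min_genes`
  genes; 1000 by default, which presumes a genome-scale gene universe.
  Synthetic runs on the ~300-gene simulated panel scale this to 50 — the
  same ~5% of the universe — via `default_synthetic_config`.
* **Normalization**: `value = ln(1 + count · 10⁴ / cell_total)`; natural
  log, scale factor 10⁴.
* **Variable genes**: per gene, mean and dispersion (variance/mean) of
  `expm1(value)`; genes split into 20 equal-frequency bins of mean
  expression; log dispersion z-scored within each bin; genes with z > 1
  selected, ranked by z, ties broken by gene id.  On small gene panels
  (hundreds of genes) markers concentrate inside the top mean bins and the
  within-bin z-score loses them, so the orchestrated pipeline falls back to
  all genes when fewer than 50 variable genes are found; selection behaves
  as intended on genome-scale panels where any one bin is dominated by
  non-markers.
* **PCA**: selected genes are centred and scaled to unit variance;
  decomposition by SVD; component signs fixed so each loading vector's
  largest-magnitude entry is positive, making results bit-reproducible.

### Jackstraw PC significance

In each of `n_replicates` (default 100) replicates, a random 1% of the
genes (at least one) is permuted across cells and the decomposition is
recomputed with the permuted genes participating.  If a PC carries no
structure, a permuted gene is exchangeable with every real gene within
that same replicate decomposition, so the rank of its absolute loading
among all genes is uniform; if the PC reflects real structure, permutation
destroys the gene's alignment and permuted genes are depleted from the top
ranks.  Each PC's statistic is therefore the fraction of permuted-gene
draws whose within-replicate loading rank lands in the top 25% of genes.

One subtlety dictates the aggregation: all of a PC's draws share the same
underlying dataset, whose chance eigen-alignment shifts them together, so
the fractions are overdispersed relative to a binomial and any test that
assumes independent draws against a fixed reference (for example, pooling
per-gene empirical p-values computed against one shared permutation null
and applying a proportion test) overstates significance — on pure-noise
data such constructions produced PC p-values in the 10⁻⁶ range.  The
implementation instead standardizes each PC's fraction against the median
and MAD of the fractions across all tested PCs — null PCs dominate that
spread and carry the same chance-alignment variability — with the plain
binomial standard error as a floor on the scale, and takes the one-sided
normal tail.  Measured behavior: false-positive rate 0.065 at α = 0.05
over 20 seeded null runs (consistent with a Binomial at α), a planted
factor detected at p ≈ 10⁻²², and no significant PC on pure noise at the
default α = 6.02 × 10⁻⁵.  The scheme assumes most tested PCs are null; if
nearly all 20 tested PCs carried signal the MAD would inflate and the test
would turn conservative.  The default α is kept as a plain configurable
threshold.

### Clustering and markers

Cells are embedded in the significant PCs (the orchestrated run falls back
to the first 10 PCs when none reach the threshold), joined in a k = 20
nearest-neighbor graph reweighted by the Jaccard overlap of neighbor sets
(edges below 1/15 pruned), and partitioned by seeded Leiden optimization of
modularity at resolution 0.8.  Labels are relabeled by decreasing cluster
size, so ids are deterministic but need not match any generating labels.

Markers are detected one-vs-rest per cluster: genes whose in-cluster vs
out-of-cluster mean normalized expression differs by at least 0.25 natural
log units are tested with the two-sided Wilcoxon rank-sum test and
Benjamini–Hochberg adjusted across the whole table.  The fold-change
threshold is applied to candidates before testing, mirroring the screening
convention, so the BH adjustment is conditional on passing the threshold.

## Connectivity screen

Per cluster, each gene gets a mean normalized expression and a detection
fraction (share of cells with nonzero expression).  A gene is "present" in
a cluster when detection ≥ 0.1 *and* mean ≥ 0.25; the dual rule is used
because either criterion alone is fragile at small cluster sizes, and both
thresholds are configuration keys.  Interaction counts per ordered
(sender, receiver) cluster pair count database pairs whose ligand is
present in the sender and receptor present in the receiver; both
orientations are obtained by listing both cluster sets on both sides, and
a per-sender mean over receivers is available as a summary.  Pairs naming
genes absent from the matrix are skipped and reported rather than raised,
since curated pair databases routinely exceed the detected gene set.
Pairings are ranked by `mean(ligand, sender) · mean(receptor, receiver)` —
the simplest score monotone in both sides — with lexicographic tie-breaks
for determinism and a top-K selector (default 50).  No permutation test of
interaction specificity is attempted, and annotation-based enrichment of
the top pairings is out of scope; the ranked table is the hand-off
artifact.

## Synthetic data

* **Video**: a centred disc of radius `R·(1 + A·sin(2πt/P))` at foreground
  intensity on a darker background, with a 1-pixel anti-aliased linear edge
  ramp so sub-pixel radius changes move pixel values (the contraction score
  then responds smoothly to amplitude), plus i.i.d. Gaussian noise added
  after rendering and clipped to [0, 1] (mimicking camera saturation).
  Defaults: 60 frames of 64×64, base radius 20 px, period 20 frames,
  noise sd 0.01.  The orchestrated run simulates five experimental groups
  of three videos, with amplitudes 0.20/0.10/0.08/0.02/0.02 chosen so that
  co-culture-like groups contract visibly more than monoculture-like ones.
* **Expression**: negative-binomial counts parameterized by mean and
  dispersion (variance = μ + μ²·φ, φ = 0.1 by default; the standard
  overdispersion model), 4 clusters × 100 cells, 300 genes, baseline mean
  5 counts.  Each cluster gets 10 dedicated marker genes inflated by
  `exp(1.0)` in that cluster.  Ligand/receptor genes named by the planted
  channels sit on a near-silent background (mean 0.02 counts) and are
  inflated by the same factor in their sender/receiver cluster, so
  presence calls at the default thresholds separate role from non-role
  clusters; a block of 20 equally near-silent genes serves as the decoy
  pool for the pair database.  Labels record the generating cluster.
* **Pair database**: the planted channels plus decoy pairs drawn without
  replacement from the decoy pool; duplicate pairs are rejected.

Every generator is a pure function of (params, seed); the pipeline derives
independent per-stage substream seeds from one global seed by hashing, so
each stage is individually reproducible.

What the simulations do not emulate: ambient RNA, doublets, batch effects,
library-size gradients correlated with cell state, organoid drift or focus
changes in the videos, and realistic gene-gene correlation structure.
Passing tests therefore demonstrate correctness of the computations and
recovery under the stated generative model, not robustness to those
real-data artifacts.

## Problem sizes and numerical conventions

Tests and the acceptance script use deliberately modest sizes chosen to
exercise each method's behavior: 10×16×16 stacks (100 of them) for the
heat-map oracle; 200 cells × 500 genes with 100 replicates for the
jackstraw planted-factor and noise checks; 3 clusters × 200 cells for
marker recovery; 4 clusters × 100 cells for the end-to-end run.  Degenerate
inputs are handled explicitly: videos shorter than lag+1 frames, empty
masks, zero-total cells, all-cells-removed filters and single-cell clusters
raise descriptive errors; fewer genes than dispersion bins, excess
requested PCs and k-neighbors larger than the cell count are reduced with
warnings.  Ties are broken lexicographically wherever a ranking is
emitted.
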