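# myoconnect

Analysis toolkit for skeletal-muscle organoid studies that combine
time-lapse contraction imaging with single-cell RNA sequencing.  It covers
three computations that such studies run in-house:

1. **Contraction quantification ("change heat").**  A bright-field video of
   a contracting organoid is reduced to a per-pixel motion map
   `heat(x, y) = (1 / (T − ℓ)) · Σ_t |I(t+ℓ, x, y) − I(t, x, y)|`
   — the mean absolute grayscale difference between frames a lag ℓ apart
   (default ℓ = 4 frames) — and to a scalar contraction score, the spatial
   mean of the heat map.  Groups of organoids (e.g. co-culture vs
   monoculture) are compared by one-way ANOVA.
2. **Single-cell preprocessing and clustering.**  Gene filter (count > 1 in
   ≥ 3 cells), cell filter (≥ 1000 expressed genes), per-cell
   log-normalization `ln(1 + c·10⁴/total)`, dispersion-based variable-gene
   selection, PCA, a jackstraw permutation test for principal-component
   significance (threshold 6.02 × 10⁻⁵), shared-nearest-neighbor graph
   clustering, and one-vs-rest Wilcoxon marker detection with a natural-log
   fold-change threshold of 0.25.
3. **Receptor–ligand connectivity screen.**  Given cluster labels and a
   ligand–receptor pair database, each gene is called present/absent per
   cluster (detection fraction ≥ 0.1 and mean expression ≥ 0.25 by
   default); the number of potential interactions is counted for every
   ordered (sender, receiver) cluster pair
   `count(s, r) = |{(l, r′) ∈ DB : present(l, s) ∧ present(r′, r)}|`,
   and pairings are ranked by the product of sender-ligand and
   receiver-receptor mean expression (top 50 reported by default).

Because raw organoid videos and sequencing data of such studies are rarely
deposited, the package ships a first-class synthetic-data module: an
oscillating-disc contraction video with tunable amplitude and camera noise,
a negative-binomial count simulator with planted cluster markers and
planted ligand–receptor channels, and a pair-database generator with decoy
pairs — so every stage is testable against known ground truth.

## Worked example

Generate a synthetic dataset, score its contraction video, and run the full
pipeline:

```sh
$ myoconnect synth --seed 7 --out synth
wrote synthetic dataset to synth

$ myoconnect moveheat run --video synth/video.tiff --group demo --out mh
video: score=0.041366 (lag=4, pairs=56)

$ myoconnect run-all --synthetic --seed 7 --out full
run complete: 72 artifacts in full
```

The contraction score 0.041 is the whole-frame mean of the change-heat
map: the average per-pixel grayscale change between frames four apart, so 0
means a static video and larger values mean stronger motion.  The full run
writes a QC report,

```
{'genes_before': 300, 'genes_after': 280, 'cells_before': 400,
 'cells_after': 400, 'n_variable_genes': 51, 'n_clusters': 4}
```

showing 20 near-silent genes removed by the gene filter and the four
simulated cell populations recovered as four clusters.  The contraction
ANOVA table (`full/contraction_anova.csv`) compares five simulated
experimental groups of three videos each:

```
group  n     mean       sd            F      p_value significance
   MR  3 0.071731 0.000010 5.080997e+06 1.730237e-31          ***
   TM  3 0.041371 0.000019 5.080997e+06 1.730237e-31          ***
   ...
```

— the group simulated with the largest contraction amplitude (MR) scores
highest, and the group means separate far beyond the *** (p < 0.001)
level.  The ranked pairing table (`full/top_pairings.csv`) puts the two
planted ligand–receptor channels at the top, ahead of every decoy pair:

```
ligand receptor  sender  receiver     score
  LIG0     REC0       3         1 18.693004
  LIG1     REC1       0         1 15.060853
```

(cluster ids are relabeled by decreasing size, so the detected sender ids
need not equal the generating ids).

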