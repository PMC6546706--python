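"""Single-cell preprocessing, PC selection, clustering and marker detection.

The stages, in pipeline order:

1. gene filter — keep genes with a count > 1 in at least 3 cells;
2. cell filter — keep cells expressing at least ``min_genes`` genes;
3. log-normalization — counts scaled per cell to a fixed total (10000)
   and transformed with the natural log1p;
4. variable-gene selection — within-bin z-score of log dispersion;
5. PCA on the scaled variable genes;
6. jackstraw permutation test assigning an empirical p-value to each PC
   (significance threshold 6.02e-5 by default);
7. shared-nearest-neighbor graph clustering (seeded Leiden, modularity
   objective with a resolution parameter);
8. one-vs-rest Wilcoxon rank-sum marker detection above a natural-log
   fold-change threshold (0.25), Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "JackstrawConfig",
    "ClusterLabels",
    "PCAResult",
    "filter_genes",
    "filter_cells",
    "log_normalize",
    "find_variable_genes",
    "run_pca",
    "jackstraw_select_pcs",
    "cluster_cells",
    "find_markers",
]


@dataclass
class CountMatrix:
    """Raw gene x cell counts with gene and cell identifiers."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells array")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: ln(1 + count * scale_factor / cell_total)."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    scale_factor: float = 10000.0
    log_base: str = "e"

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class JackstrawConfig:
    """Settings of the jackstraw PC-significance permutation test."""

    alpha: float = 6.02e-5
    n_replicates: int = 100
    permuted_gene_fraction: float = 0.01
    n_pcs_tested: int = 20
    rank_tail_fraction: float = 0.25  # top loading-rank band tested for depletion
    seed: int = 0

    def validate(self, n_genes: int) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 < self.permuted_gene_fraction <= 1:
            raise ValueError("permuted_gene_fraction must lie in (0, 1]")
        if int(round(self.permuted_gene_fraction * n_genes)) < 1 and n_genes:
            # at least one gene must be permuted per replicate
            pass  # handled by max(1, ...) at draw time
        if self.n_replicates < 10:
            warnings.warn(
                "fewer than 10 jackstraw replicates: empirical p resolution "
                "is coarser than typical alpha", stacklevel=2)


@dataclass
class ClusterLabels:
    """Cell -> cluster assignment with contiguous ids starting at 0."""

    assignments: pd.Series  # index: cell id, value: cluster id

    def __post_init__(self) -> None:
        self.assignments = pd.Series(self.assignments).astype(int)

    @property
    def n_clusters(self) -> int:
        return int(self.assignments.nunique())

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(self.assignments.unique())


# ---------------------------------------------------------------------------
# QC filters


def filter_genes(m: CountMatrix, min_count: int = 2, min_cells: int = 3) -> CountMatrix:
    """Keep genes with a count of at least ``min_count`` in >= ``min_cells`` cells.

    The defaults implement the rule "expression level greater than 1 in at
    least 3 cells" (a count of exactly 1 does not qualify).  Gene order is
    preserved; the cell set is unchanged.
    """
    keep = (m.counts >= min_count).sum(axis=1) >= min_cells
    if not keep.any():
        warnings.warn("gene filter removed every gene", stacklevel=2)
    kept_ids = [g for g, k in zip(m.gene_ids, keep) if k]
    logger.info("gene filter: %d/%d genes kept", keep.sum(), m.n_genes)
    return CountMatrix(counts=m.counts[keep], gene_ids=kept_ids,
                       cell_ids=list(m.cell_ids), provenance=m.provenance)


def filter_cells(m: CountMatrix, min_genes: int = 1000) -> CountMatrix:
    """Keep cells expressing (count > 0) at least ``min_genes`` genes."""
    keep = (m.counts > 0).sum(axis=0) >= min_genes
    if not keep.any():
        raise ValueError(
            f"cell filter (min_genes={min_genes}) removed all {m.n_cells} "
            "cells; review the threshold against the gene universe size"
        )
    kept_ids = [c for c, k in zip(m.cell_ids, keep) if k]
    logger.info("cell filter: %d/%d cells kept", keep.sum(), m.n_cells)
    return CountMatrix(counts=m.counts[:, keep], gene_ids=list(m.gene_ids),
                       cell_ids=kept_ids, provenance=m.provenance)


def log_normalize(m: CountMatrix, scale_factor: float = 10000.0) -> NormalizedMatrix:
    """Per-cell total-count scaling to ``scale_factor`` followed by ln(1 + x).

    value(g, c) = ln(1 + count(g, c) * scale_factor / total(c)), with totals
    computed on the matrix as given (i.e. after any filtering).  Every cell
    therefore satisfies sum_g (exp(value) - 1) = scale_factor exactly.
    """
    totals = m.counts.sum(axis=0).astype(float)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise ValueError(
            f"cell(s) with zero total counts cannot be normalized: "
            f"{[m.cell_ids[i] for i in zero[:5]]}"
        )
    values = np.log1p(m.counts * (scale_factor / totals))
    return NormalizedMatrix(values=values, gene_ids=list(m.gene_ids),
                            cell_ids=list(m.cell_ids),
                            scale_factor=scale_factor)


# ---------------------------------------------------------------------------
# Variable genes


def find_variable_genes(nm: NormalizedMatrix, n_bins: int = 20,
                        z_cutoff: float = 1.0) -> pd.DataFrame:
    """Rank genes by within-bin dispersion z-score; return those above cutoff.

    Mean and dispersion (variance/mean) are computed on expm1 of the
    normalized values; genes are split into ``n_bins`` equal-frequency bins
    of mean expression and the log dispersion is z-scored within each bin.
    Genes with z > ``z_cutoff`` are returned ranked by z descending, ties
    broken by gene id.
    """
    x = np.expm1(nm.values)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1) if nm.n_cells > 1 else np.zeros(nm.n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    log_disp = np.log1p(disp)

    n_genes = len(nm.gene_ids)
    if n_genes < n_bins:
        warnings.warn(
            f"only {n_genes} genes; reducing dispersion bins from {n_bins}",
            stacklevel=2)
        n_bins = max(1, n_genes)
    # equal-frequency bins of mean expression
    order = np.argsort(mean, kind="stable")
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(n_genes) * n_bins) // n_genes, n_bins - 1)

    z = np.zeros(n_genes)
    for b in range(n_bins):
        idx = bin_of == b
        if not idx.any():
            continue
        vals = log_disp[idx]
        sd = vals.std(ddof=0)
        if sd > 0:
            z[idx] = (vals - vals.mean()) / sd
    table = pd.DataFrame({
        "gene": nm.gene_ids, "mean": mean, "dispersion": disp,
        "dispersion_z": z,
    })
    selected = table[table.dispersion_z > z_cutoff]
    return selected.sort_values(
        ["dispersion_z", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# PCA + jackstraw


@dataclass
class PCAResult:
    """PCA of the scaled expression of a selected gene set."""

    embedding: np.ndarray           # cells x n_pcs (scores)
    loadings: np.ndarray            # genes x n_pcs
    variance_explained: np.ndarray  # fraction per PC
    genes: list[str]
    cell_ids: list[str]

    @property
    def n_pcs(self) -> int:
        return self.embedding.shape[1]


def _scale_genes(values: np.ndarray) -> np.ndarray:
    """Scale each gene (row) to mean 0, unit variance (sd ddof=1)."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mean) / sd


def _svd_pca(scaled: np.ndarray, n_pcs: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD-based PCA of a genes x cells scaled matrix.

    Returns (embedding cells x n_pcs, loadings genes x n_pcs, variance
    fraction).  Component signs are fixed so that each loading vector's
    largest-magnitude entry is positive.
    """
    X = scaled.T  # cells x genes, observations in rows (already centred)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n_pcs = min(n_pcs, S.size)
    loadings = Vt[:n_pcs].T
    # deterministic sign: largest-|.| loading entry positive per component
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0),
                            np.arange(n_pcs)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    embedding = (U[:, :n_pcs] * S[:n_pcs]) * flip
    total = (S ** 2).sum()
    var_frac = (S[:n_pcs] ** 2) / total if total > 0 else np.zeros(n_pcs)
    return embedding, loadings, var_frac


def run_pca(nm: NormalizedMatrix, genes: list[str] | None = None,
            n_pcs: int = 20) -> PCAResult:
    """PCA of the per-gene scaled normalized expression.

    Each selected gene is centred and scaled to unit variance across cells
    before decomposition.  Deterministic up to the fixed sign convention.
    """
    genes = list(genes) if genes is not None else list(nm.gene_ids)
    missing = set(genes) - set(nm.gene_ids)
    if missing:
        raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
    idx = [nm.gene_ids.index(g) for g in genes]
    sub = nm.values[idx]
    max_pcs = min(len(genes), nm.n_cells)
    if n_pcs > max_pcs:
        warnings.warn(
            f"n_pcs={n_pcs} exceeds min(genes, cells)={max_pcs}; reduced",
            stacklevel=2)
        n_pcs = max_pcs
    scaled = _scale_genes(sub)
    embedding, loadings, var_frac = _svd_pca(scaled, n_pcs)
    return PCAResult(embedding=embedding, loadings=loadings,
                     variance_explained=var_frac, genes=genes,
                     cell_ids=list(nm.cell_ids))


def jackstraw_select_pcs(
    nm: NormalizedMatrix, pca: PCAResult, cfg: JackstrawConfig,
) -> tuple[list[int], np.ndarray]:
    """Jackstraw permutation significance test for principal components.

    In each replicate a random small fraction of the PCA gene set is
    permuted across cells and the decomposition is recomputed with the
    permuted genes participating.  When a PC carries no structure, a
    permuted gene is exchangeable with every real gene inside that same
    replicate decomposition, so the rank of its absolute loading among all
    genes is uniform.  When the PC reflects real structure, permutation
    destroys a gene's alignment with it, so permuted genes are depleted
    from the top loading ranks.  Each PC's statistic is the fraction of
    permuted-gene draws (pooled over replicates) whose within-replicate
    loading rank falls in the top ``rank_tail_fraction`` of genes; under
    the null this fraction centres on ``rank_tail_fraction``.

    Chance eigen-alignment of the finite dataset shifts all of one PC's
    draws together, so the fractions are overdispersed relative to a
    binomial.  The PC-level p-value therefore standardizes each PC's
    fraction against the median and MAD of the fractions across all tested
    PCs (null PCs dominate that spread and carry the same chance-alignment
    variability), with the plain binomial standard error as a floor on the
    scale, and takes the one-sided normal tail for depletion.  Observed
    and permuted decompositions are never mixed, so eigenvalue overfitting
    cannot bias the comparison.

    Returns (indices of PCs with p < alpha, per-PC p-value array).
    """
    cfg.validate(len(pca.genes))
    rng = np.random.default_rng(cfg.seed)
    idx = [nm.gene_ids.index(g) for g in pca.genes]
    scaled = _scale_genes(nm.values[idx])
    n_genes, n_cells = scaled.shape
    n_pcs = min(cfg.n_pcs_tested, pca.n_pcs)

    n_perm = max(1, int(round(cfg.permuted_gene_fraction * n_genes)))
    q = cfg.rank_tail_fraction
    top = np.zeros(n_pcs, dtype=int)   # permuted draws landing in the top tail
    n_draws = 0
    for _ in range(cfg.n_replicates):
        chosen = rng.choice(n_genes, size=n_perm, replace=False)
        perm = scaled.copy()
        for g in chosen:
            perm[g] = perm[g, rng.permutation(n_cells)]
        # permutation preserves per-gene mean/sd, so no re-scaling needed
        _, loadings, _ = _svd_pca(perm, n_pcs)
        ranks = stats.rankdata(np.abs(loadings), axis=0)  # 1..n_genes
        norm_ranks = (ranks[chosen] - 0.5) / n_genes
        top += (norm_ranks > 1.0 - q).sum(axis=0)
        n_draws += n_perm
    frac = top / n_draws
    scale = max(stats.median_abs_deviation(frac, scale="normal"),
                np.sqrt(q * (1 - q) / n_draws))
    pc_p = stats.norm.sf((np.median(frac) - frac) / scale)
    if cfg.alpha >= 1:
        significant = list(range(n_pcs))
    else:
        significant = [j for j in range(n_pcs) if pc_p[j] < cfg.alpha]
    return significant, pc_p


# ---------------------------------------------------------------------------
# Clustering


def cluster_cells(embedding: np.ndarray, n_pcs_used: int | None = None,
                  resolution: float = 0.8, k_neighbors: int = 20,
                  seed: int = 0, cell_ids: list[str] | None = None,
                  min_snn_jaccard: float = 1 / 15) -> ClusterLabels:
    """Cluster cells by community detection on a shared-nearest-neighbor graph.

    A k-nearest-neighbor graph (Euclidean, on the leading ``n_pcs_used``
    embedding columns) is reweighted by the Jaccard overlap of neighbor
    sets; edges below ``min_snn_jaccard`` are pruned.  Communities are found
    with seeded Leiden optimization of modularity at the given resolution
    and relabeled by decreasing size.
    """
    X = np.asarray(embedding, dtype=float)
    if n_pcs_used is not None:
        X = X[:, :n_pcs_used]
    n = X.shape[0]
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(n)]
    k = k_neighbors
    if n <= k:
        warnings.warn(
            f"{n} cells <= k_neighbors={k_neighbors}; reducing k to {n - 1}",
            stacklevel=2)
        k = max(1, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    knn = nn.kneighbors(return_distance=False)
    # neighbor sets include the cell itself (standard SNN convention)
    sets = [set(row) | {i} for i, row in enumerate(knn)]
    edges, weights = [], []
    for i, row in enumerate(knn):
        for j in row:
            if j <= i:
                continue
            inter = len(sets[i] & sets[j])
            jac = inter / len(sets[i] | sets[j])
            if jac >= min_snn_jaccard:
                edges.append((i, int(j)))
                weights.append(jac)
    g = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition, weights=weights,
        resolution_parameter=resolution, seed=seed)
    raw = np.array(part.membership)
    # contiguous ids ordered by decreasing cluster size (ties by old id)
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=cell_ids,
                       name="cluster")
    return ClusterLabels(assignments=labels)


# ---------------------------------------------------------------------------
# Markers


def find_markers(nm: NormalizedMatrix, labels: ClusterLabels | pd.Series,
                 logfc_threshold: float = 0.25,
                 alpha: float = 0.05) -> pd.DataFrame:
    """One-vs-rest cluster marker detection.

    For every cluster, each gene whose in-cluster vs out-of-cluster mean
    normalized expression differs by at least ``logfc_threshold`` (natural
    log units) is tested with the two-sided Wilcoxon rank-sum test;
    p-values are Benjamini-Hochberg adjusted across the full table.

    Returns a DataFrame with columns gene, cluster, log_fc, p_value,
    p_adjusted, pct_in, pct_out, sorted by cluster then adjusted p.
    """
    assign = labels.assignments if isinstance(labels, ClusterLabels) else pd.Series(labels)
    assign = assign.reindex(nm.cell_ids)
    if assign.isna().any():
        raise ValueError("labels do not cover every cell in the matrix")
    clusters = sorted(assign.unique())
    if len(clusters) < 2:
        raise ValueError("marker detection needs at least 2 clusters")

    lab = assign.to_numpy()
    values = nm.values
    detected = values > 0
    rows = []
    for k in clusters:
        in_mask = lab == k
        if in_mask.sum() < 2:
            warnings.warn(f"cluster {k} has < 2 cells; skipped", stacklevel=2)
            continue
        out_mask = ~in_mask
        mean_in = values[:, in_mask].mean(axis=1)
        mean_out = values[:, out_mask].mean(axis=1)
        log_fc = mean_in - mean_out
        cand = np.where(np.abs(log_fc) >= logfc_threshold)[0]
        for gi in cand:
            p = stats.mannwhitneyu(values[gi, in_mask], values[gi, out_mask],
                                   alternative="two-sided").pvalue
            rows.append({
                "gene": nm.gene_ids[gi],
                "cluster": k,
                "log_fc": log_fc[gi],
                "p_value": p,
                "pct_in": detected[gi, in_mask].mean(),
                "pct_out": detected[gi, out_mask].mean(),
            })
    table = pd.DataFrame(
        rows, columns=["gene", "cluster", "log_fc", "p_value", "pct_in",
                       "pct_out"])
    if len(table):
        table["p_adjusted"] = multipletests(table.p_value, method="fdr_bh")[1]
    else:
        table["p_adjusted"] = pd.Series(dtype=float)
    table = table.sort_values(["cluster", "p_adjusted", "gene"]).reset_index(
        drop=True)
    return table[["gene", "cluster", "log_fc", "p_value", "p_adjusted",
                  "pct_in", "pct_out"]]
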