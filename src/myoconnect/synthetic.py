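"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* a contraction video — a centred bright disc whose radius oscillates
  sinusoidally over a dark background, plus optional Gaussian pixel noise —
  standing in for bright-field organoid recordings;
* a gene x cell count matrix of negative-binomial counts with planted
  per-cluster marker genes and planted ligand/receptor channels between
  chosen sender/receiver clusters;
* a ligand-receptor pair database mixing the planted channels with decoy
  pairs drawn from silent genes.

Every generator is a pure function of (params, seed): identical inputs give
bit-identical outputs.  Independent substreams are spawned from the one
seed so stages stay reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .moveheat import FrameStack
from .scrna import CountMatrix

__all__ = [
    "VideoSimParams",
    "ExprSimParams",
    "PlantedTruth",
    "LRChannel",
    "generate_contraction_video",
    "generate_expression_dataset",
    "generate_lr_database",
]


@dataclass(frozen=True)
class VideoSimParams:
    """Parameters of the oscillating-disc contraction video.

    The disc radius at frame t is ``base_radius * (1 + amplitude *
    sin(2 pi t / period))``; amplitude is a fraction of the base radius.
    Gaussian noise of sd ``noise_sigma`` (intensity units) is added after
    rendering and clipped to [0, 1], mimicking camera saturation.
    """

    n_frames: int = 60
    height: int = 64
    width: int = 64
    base_radius: float = 20.0
    amplitude: float = 0.1
    period: float = 20.0
    noise_sigma: float = 0.01
    foreground: float = 0.8
    background: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 5:
            raise ValueError("n_frames must be >= 5 (at least one lag-4 pair)")
        if self.height <= 0 or self.width <= 0:
            raise ValueError("frame dimensions must be positive")
        if not 0 <= self.amplitude < 1:
            raise ValueError("amplitude must satisfy 0 <= A < 1")
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        max_r = self.base_radius * (1 + self.amplitude)
        if max_r > min(self.height, self.width) / 2:
            raise ValueError(
                f"disc (max radius {max_r:.1f}) exceeds frame bounds "
                f"{self.height}x{self.width}"
            )
        for name in ("foreground", "background"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} intensity must lie in [0, 1]")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _render_disc(height: int, width: int, radius: float,
                 fg: float, bg: float) -> np.ndarray:
    """Disc with a 1-pixel anti-aliased linear edge ramp.

    The ramp makes pixel values respond to sub-pixel radius changes, so the
    change-heat statistic varies smoothly with contraction amplitude.
    """
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    yy, xx = np.mgrid[0:height, 0:width]
    dist = np.hypot(yy - cy, xx - cx)
    cover = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    return bg + (fg - bg) * cover


def generate_contraction_video(params: VideoSimParams) -> FrameStack:
    """Render the oscillating-disc video described by ``params``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    t = np.arange(params.n_frames)
    radii = params.base_radius * (
        1.0 + params.amplitude * np.sin(2 * np.pi * t / params.period)
    )
    frames = np.stack([
        _render_disc(params.height, params.width, r,
                     params.foreground, params.background)
        for r in radii
    ])
    if params.noise_sigma > 0:
        frames = frames + rng.normal(0.0, params.noise_sigma, frames.shape)
    frames = np.clip(frames, 0.0, 1.0)
    return FrameStack(frames=frames,
                      source_id=f"synthetic-disc-seed{params.seed}")


@dataclass(frozen=True)
class LRChannel:
    """One planted ligand-receptor communication channel."""

    ligand: str
    receptor: str
    sender: int
    receiver: int


@dataclass(frozen=True)
class ExprSimParams:
    """Parameters of the clustered negative-binomial count simulator.

    Counts are negative-binomial with variance ``mu + mu^2 * dispersion``
    (the standard scRNA-seq overdispersion model; dispersion -> 0 recovers
    Poisson).  Each cluster gets ``marker_genes_per_cluster`` dedicated
    marker genes whose mean is inflated by ``exp(marker_log_fold_change)``
    in that cluster.  Ligand/receptor genes named by ``planted_lr_channels``
    sit on a near-silent background (``lr_background_mean``) and are
    inflated by the same factor in their sender (ligand) or receiver
    (receptor) cluster.  A block of ``n_silent_genes`` equally near-silent
    genes provides a decoy pool for the pair database.
    """

    n_clusters: int = 4
    cells_per_cluster: int = 100
    n_genes: int = 300
    marker_genes_per_cluster: int = 10
    marker_log_fold_change: float = 1.0
    nb_dispersion: float = 0.1
    baseline_mean: float = 5.0
    planted_lr_channels: tuple[LRChannel, ...] = ()
    lr_background_mean: float = 0.02
    n_silent_genes: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.cells_per_cluster < 1:
            raise ValueError("cells_per_cluster must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        n_marker = self.n_clusters * self.marker_genes_per_cluster
        lr_genes = {g for ch in self.planted_lr_channels
                    for g in (ch.ligand, ch.receptor)}
        if n_marker + len(lr_genes) + self.n_silent_genes > self.n_genes:
            raise ValueError(
                "n_genes too small for markers + LR genes + silent block"
            )
        for ch in self.planted_lr_channels:
            for k in (ch.sender, ch.receiver):
                if not 0 <= k < self.n_clusters:
                    raise ValueError(
                        f"channel {ch} references invalid cluster {k}"
                    )
        if len(lr_genes) != 2 * len(self.planted_lr_channels):
            # same gene reused across channels is allowed only if roles match
            ligs = {c.ligand for c in self.planted_lr_channels}
            recs = {c.receptor for c in self.planted_lr_channels}
            if ligs & recs:
                raise ValueError("a gene cannot be both ligand and receptor")


@dataclass
class PlantedTruth:
    """Ground truth of one simulated expression dataset."""

    marker_genes: dict[int, list[str]]       # cluster -> its marker gene ids
    channels: list[LRChannel]                 # planted L-R channels
    true_means: pd.DataFrame                  # genes x clusters generating means
    decoy_pool: list[str]                     # silent genes usable as decoys

    def markers_of(self, cluster: int) -> list[str]:
        return self.marker_genes.get(cluster, [])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + mu^2 * dispersion."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def generate_expression_dataset(
    params: ExprSimParams,
) -> tuple[CountMatrix, pd.Series, PlantedTruth]:
    """Simulate a clustered count matrix with planted markers and channels.

    Returns the count matrix, a cell-id -> cluster label Series (the
    generating assignment), and the :class:`PlantedTruth` oracle.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    K = params.n_clusters
    n_cells = K * params.cells_per_cluster
    labels = np.repeat(np.arange(K), params.cells_per_cluster)

    gene_ids = [f"G{i:04d}" for i in range(params.n_genes)]
    n_marker = K * params.marker_genes_per_cluster
    marker_genes = {
        k: gene_ids[k * params.marker_genes_per_cluster:
                    (k + 1) * params.marker_genes_per_cluster]
        for k in range(K)
    }
    # rename LR genes onto the indices after the marker block, in channel order
    lr_names: list[str] = []
    for ch in params.planted_lr_channels:
        for g in (ch.ligand, ch.receptor):
            if g not in lr_names:
                lr_names.append(g)
    for j, name in enumerate(lr_names):
        gene_ids[n_marker + j] = name
    silent_start = n_marker + len(lr_names)
    silent_genes = gene_ids[silent_start:silent_start + params.n_silent_genes]

    # genes x clusters table of generating means
    mu = np.full((params.n_genes, K), params.baseline_mean)
    fold = np.exp(params.marker_log_fold_change)
    for k, genes in marker_genes.items():
        for g in genes:
            mu[gene_ids.index(g), k] *= fold
    lr_rows = {name: n_marker + j for j, name in enumerate(lr_names)}
    for name, row in lr_rows.items():
        mu[row, :] = params.lr_background_mean
    for ch in params.planted_lr_channels:
        mu[lr_rows[ch.ligand], ch.sender] = params.baseline_mean * fold
        mu[lr_rows[ch.receptor], ch.receiver] = params.baseline_mean * fold
    for g in silent_genes:
        mu[gene_ids.index(g), :] = params.lr_background_mean

    counts = np.empty((params.n_genes, n_cells), dtype=np.int64)
    for k in range(K):
        cols = np.where(labels == k)[0]
        cell_mu = np.broadcast_to(mu[:, [k]], (params.n_genes, cols.size))
        counts[:, cols] = _nb_draw(rng, cell_mu, params.nb_dispersion)

    cell_ids = [f"cell{j:04d}" for j in range(n_cells)]
    matrix = CountMatrix(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids,
                         provenance=f"synthetic-nb-seed{params.seed}")
    label_series = pd.Series(labels, index=cell_ids, name="cluster")
    truth = PlantedTruth(
        marker_genes=marker_genes,
        channels=list(params.planted_lr_channels),
        true_means=pd.DataFrame(mu, index=gene_ids,
                                columns=[f"cluster{k}" for k in range(K)]),
        decoy_pool=list(silent_genes),
    )
    return matrix, label_series, truth


def generate_lr_database(
    planted: Sequence[LRChannel | tuple[str, str]],
    n_decoys: int,
    seed: int = 0,
    decoy_pool: Sequence[str] = (),
) -> pd.DataFrame:
    """Build a ligand-receptor pair table: planted pairs plus decoys.

    Decoy ligands and receptors are sampled (without replacement) from
    ``decoy_pool``, which must contain genes not expressed anywhere, so a
    correct screen assigns decoy pairs zero interactions.

    Returns a DataFrame with columns ``ligand``, ``receptor``, ``annotation``.
    """
    pairs = [(p.ligand, p.receptor) if isinstance(p, LRChannel) else tuple(p)
             for p in planted]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate planted (ligand, receptor) pairs")
    planted_genes = {g for pair in pairs for g in pair}
    if set(decoy_pool) & planted_genes:
        raise ValueError("decoy_pool overlaps planted pair genes")
    if n_decoys > 0:
        if 2 * n_decoys > len(decoy_pool):
            raise ValueError(
                f"decoy_pool of {len(decoy_pool)} genes cannot supply "
                f"{n_decoys} disjoint decoy pairs"
            )
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(decoy_pool), size=2 * n_decoys, replace=False)
        pool = [decoy_pool[i] for i in chosen]
        decoys = list(zip(pool[:n_decoys], pool[n_decoys:]))
    else:
        decoys = []
    rows = [
        {"ligand": l, "receptor": r, "annotation": "planted"}
        for l, r in pairs
    ] + [
        {"ligand": l, "receptor": r, "annotation": "decoy"}
        for l, r in decoys
    ]
    db = pd.DataFrame(rows, columns=["ligand", "receptor", "annotation"])
    if db[["ligand", "receptor"]].duplicated().any():
        raise ValueError("duplicate (ligand, receptor) rows after decoy draw")
    return db
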