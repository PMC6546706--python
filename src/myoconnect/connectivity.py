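"""In silico receptor-ligand connectivity screen between cell clusters.

Given per-cluster expression profiles and a ligand-receptor pair database,
the screen (i) calls each gene present or absent in each cluster using a
dual detection-fraction / mean-expression rule, (ii) counts, for every
ordered (sender, receiver) cluster pair, the database pairs whose ligand is
present in the sender and receptor present in the receiver, and (iii) ranks
pairings by the product of sender-ligand and receiver-receptor mean
expression, with a top-K selector (default 50).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib
import numpy as np
import pandas as pd

from .scrna import ClusterLabels, NormalizedMatrix

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = [
    "ClusterProfile",
    "PresenceCalls",
    "InteractionMap",
    "build_cluster_profile",
    "call_presence",
    "count_interactions",
    "score_pairings",
    "render_interaction_heatmap",
    "read_lr_database",
]


@dataclass
class ClusterProfile:
    """Per-cluster mean expression and detection fraction per gene."""

    mean: pd.DataFrame        # genes x clusters, mean normalized expression
    detection: pd.DataFrame   # genes x clusters, fraction of cells with count > 0
    n_cells: pd.Series        # cells per cluster

    @property
    def clusters(self) -> list:
        return list(self.mean.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.mean.index)


@dataclass
class PresenceCalls:
    """Boolean expressed/absent call per (gene, cluster) plus the policy."""

    expressed: pd.DataFrame   # genes x clusters booleans
    min_detection_fraction: float
    min_mean: float


@dataclass
class InteractionMap:
    """Ordered cluster-pair interaction counts and contributing pairs."""

    counts: pd.DataFrame                       # senders (rows) x receivers
    contributing: dict[tuple, list[tuple[str, str]]]
    skipped_pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for s in self.counts.index:
            for r in self.counts.columns:
                got = len(self.contributing.get((s, r), []))
                if got != int(self.counts.loc[s, r]):
                    raise ValueError(
                        f"count/list mismatch for pair ({s}, {r})"
                    )

    def mean_per_sender(self) -> pd.Series:
        """Mean interaction count over receiver clusters, per sender."""
        return self.counts.mean(axis=1)


def build_cluster_profile(nm: NormalizedMatrix,
                          labels: ClusterLabels | pd.Series) -> ClusterProfile:
    """Summarize normalized expression per cluster.

    For every gene and cluster: the mean normalized value over the
    cluster's cells and the fraction of those cells with nonzero
    expression.
    """
    assign = labels.assignments if isinstance(labels, ClusterLabels) else pd.Series(labels)
    missing = set(assign.index) - set(nm.cell_ids)
    if missing:
        raise KeyError(
            f"labels reference cells absent from the matrix: "
            f"{sorted(missing)[:5]}"
        )
    assign = assign.reindex(nm.cell_ids)
    if assign.isna().any():
        raise ValueError("labels do not cover every cell in the matrix")
    lab = assign.to_numpy()
    clusters = sorted(pd.unique(assign))
    means, dets, sizes = {}, {}, {}
    for k in clusters:
        cols = lab == k
        means[k] = nm.values[:, cols].mean(axis=1)
        dets[k] = (nm.values[:, cols] > 0).mean(axis=1)
        sizes[k] = int(cols.sum())
    return ClusterProfile(
        mean=pd.DataFrame(means, index=nm.gene_ids),
        detection=pd.DataFrame(dets, index=nm.gene_ids),
        n_cells=pd.Series(sizes),
    )


def call_presence(profile: ClusterProfile,
                  min_detection_fraction: float = 0.1,
                  min_mean: float = 0.25) -> PresenceCalls:
    """Call a gene present in a cluster if both thresholds are met.

    expressed(g, k) <=> detection_fraction(g, k) >= min_detection_fraction
    AND mean(g, k) >= min_mean.  The dual rule is robust at small cluster
    sizes where either criterion alone is fragile.
    """
    if not 0 <= min_detection_fraction <= 1:
        raise ValueError("min_detection_fraction must lie in [0, 1]")
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    expressed = (profile.detection >= min_detection_fraction) & (
        profile.mean >= min_mean)
    return PresenceCalls(expressed=expressed,
                         min_detection_fraction=min_detection_fraction,
                         min_mean=min_mean)


def _validate_clusters(requested: Sequence, known: Iterable) -> list:
    known = set(known)
    bad = [c for c in requested if c not in known]
    if bad:
        raise KeyError(f"unknown cluster id(s): {bad}")
    return list(requested)


def count_interactions(calls: PresenceCalls, db: pd.DataFrame,
                       senders: Sequence, receivers: Sequence) -> InteractionMap:
    """Count potential interactions per ordered (sender, receiver) pair.

    count(s, r) = number of database pairs (ligand, receptor) with the
    ligand called present in sender cluster s and the receptor present in
    receiver cluster r.  Pairs whose ligand or receptor is absent from the
    profiled gene set are skipped and reported, not errors.
    """
    senders = _validate_clusters(senders, calls.expressed.columns)
    receivers = _validate_clusters(receivers, calls.expressed.columns)
    genes = set(calls.expressed.index)
    contributing: dict[tuple, list[tuple[str, str]]] = {
        (s, r): [] for s in senders for r in receivers}
    skipped: list[tuple[str, str]] = []
    for lig, rec in zip(db["ligand"], db["receptor"]):
        if lig not in genes or rec not in genes:
            skipped.append((lig, rec))
            continue
        for s in senders:
            if not calls.expressed.at[lig, s]:
                continue
            for r in receivers:
                if calls.expressed.at[rec, r]:
                    contributing[(s, r)].append((lig, rec))
    counts = pd.DataFrame(
        [[len(contributing[(s, r)]) for r in receivers] for s in senders],
        index=pd.Index(senders, name="sender"),
        columns=pd.Index(receivers, name="receiver"),
    )
    return InteractionMap(counts=counts, contributing=contributing,
                          skipped_pairs=skipped)


def score_pairings(profile: ClusterProfile, db: pd.DataFrame,
                   senders: Sequence, receivers: Sequence,
                   top_k: int | None = None) -> pd.DataFrame:
    """Rank ligand-receptor pairings by expression product.

    score(l, r, s, rcv) = mean(l, s) * mean(r, rcv) over all database pairs
    and ordered sender/receiver cluster combinations.  Sorted by score
    descending, ties broken lexicographically by (ligand, receptor, sender,
    receiver) for determinism.  ``top_k`` returns the head of the ranking
    (the screen's reported selection uses 50).
    """
    senders = _validate_clusters(senders, profile.mean.columns)
    receivers = _validate_clusters(receivers, profile.mean.columns)
    genes = set(profile.mean.index)
    rows = []
    for lig, rec in zip(db["ligand"], db["receptor"]):
        if lig not in genes or rec not in genes:
            continue
        for s in senders:
            for r in receivers:
                rows.append({
                    "ligand": lig, "receptor": rec,
                    "sender": s, "receiver": r,
                    "score": profile.mean.at[lig, s] * profile.mean.at[rec, r],
                })
    table = pd.DataFrame(
        rows, columns=["ligand", "receptor", "sender", "receiver", "score"])
    table = table.sort_values(
        ["score", "ligand", "receptor", "sender", "receiver"],
        ascending=[False, True, True, True, True],
    ).reset_index(drop=True)
    if top_k is not None:
        table = table.head(top_k)
    return table


def render_interaction_heatmap(imap: InteractionMap,
                               out_path: str | Path) -> tuple[Path, Path]:
    """Write the interaction-count matrix as CSV plus a PNG heatmap.

    The PNG uses a linear color scale annotated with the matrix min/max; a
    sidecar JSON records the scale (and flags a degenerate min == max map).
    Returns (png_path, csv_path).
    """
    out_path = Path(out_path)
    csv_path = out_path.with_suffix(".csv")
    imap.counts.to_csv(csv_path)
    vmin = float(imap.counts.values.min())
    vmax = float(imap.counts.values.max())
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(imap.counts.values, cmap="viridis", vmin=vmin,
                   vmax=vmax if vmax > vmin else vmin + 1)
    ax.set_xticks(range(len(imap.counts.columns)),
                  [str(c) for c in imap.counts.columns])
    ax.set_yticks(range(len(imap.counts.index)),
                  [str(c) for c in imap.counts.index])
    ax.set_xlabel("receiver cluster")
    ax.set_ylabel("sender cluster")
    ax.set_title(f"potential interactions (min={vmin:g}, max={vmax:g})")
    fig.colorbar(im, ax=ax)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    sidecar = {"scale_min": vmin, "scale_max": vmax,
               "degenerate_scale": vmin == vmax,
               "n_skipped_pairs": len(imap.skipped_pairs)}
    out_path.with_suffix(out_path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))
    return out_path, csv_path


def read_lr_database(path: str | Path) -> pd.DataFrame:
    """Read a ligand-receptor pair TSV (columns: ligand, receptor[, annotation])."""
    db = pd.read_csv(path, sep="\t", dtype=str)
    required = {"ligand", "receptor"}
    if not required <= set(db.columns):
        raise ValueError(
            f"pair database must have columns {sorted(required)}, "
            f"got {list(db.columns)}"
        )
    if db[["ligand", "receptor"]].duplicated().any():
        raise ValueError("duplicate (ligand, receptor) rows in pair database")
    if db[["ligand", "receptor"]].isna().any().any() or (
            db[["ligand", "receptor"]] == "").any().any():
        raise ValueError("empty gene id in pair database")
    return db
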