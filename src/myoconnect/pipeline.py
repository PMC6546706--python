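"""End-to-end orchestration: synthetic generation -> single-cell pipeline ->
connectivity screen -> contraction quantification, with a run manifest.

Each stage writes its artifacts under the configured output directory; the
manifest records the config snapshot, per-file SHA-256 checksums, record
counts and timestamps.  Re-running with an identical config and seed
reproduces identical checksums.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import connectivity as conn
from . import io as mio
from . import moveheat as mh
from . import scrna
from .config import PipelineConfig
from .synthetic import (ExprSimParams, LRChannel, VideoSimParams,
                        generate_contraction_video, generate_expression_dataset,
                        generate_lr_database)

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_all"]


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    version: str
    checksums: dict[str, str] = field(default_factory=dict)
    record_counts: dict[str, int] = field(default_factory=dict)
    timestamps: dict[str, str] = field(default_factory=dict)

    def add_file(self, path: Path, root: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.checksums[str(path.relative_to(root))] = digest

    def stamp(self, stage: str) -> None:
        self.timestamps[stage] = datetime.datetime.now(
            datetime.timezone.utc).isoformat()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps({
            "version": self.version,
            "config": self.config,
            "checksums": dict(sorted(self.checksums.items())),
            "record_counts": self.record_counts,
            "timestamps": self.timestamps,
        }, indent=2, default=str))


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _derive_seed(seed: int, stage: str) -> int:
    """Independent per-stage substream seed from the one global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute every stage on synthetic inputs and write all artifacts.

    Returns the manifest (also written to ``<out_dir>/manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__)
    stage = "init"
    try:
        # ---- synthetic inputs -------------------------------------------
        stage = "synth"
        manifest.stamp(stage)
        channels = tuple(LRChannel(*c) for c in config.synth.planted_lr_channels)
        expr_params = ExprSimParams(
            n_clusters=config.synth.n_clusters,
            cells_per_cluster=config.synth.cells_per_cluster,
            n_genes=config.synth.n_genes,
            marker_genes_per_cluster=config.synth.marker_genes_per_cluster,
            marker_log_fold_change=config.synth.marker_log_fold_change,
            nb_dispersion=config.synth.nb_dispersion,
            baseline_mean=config.synth.baseline_mean,
            n_silent_genes=config.synth.n_silent_genes,
            planted_lr_channels=channels,
            seed=_derive_seed(config.seed, "expression"),
        )
        raw, true_labels, truth = generate_expression_dataset(expr_params)
        db = generate_lr_database(
            truth.channels, config.synth.n_decoy_pairs,
            seed=_derive_seed(config.seed, "lrdb"),
            decoy_pool=truth.decoy_pool)
        mio.write_expression(raw, out / "raw_counts", format="mtx")
        mio.write_labels(true_labels, out / "true_labels.tsv")
        mio.write_truth(truth, out / "truth.json")
        db.to_csv(out / "lr_pairs.tsv", sep="\t", index=False)
        manifest.record_counts["synth.genes"] = raw.n_genes
        manifest.record_counts["synth.cells"] = raw.n_cells
        manifest.record_counts["synth.lr_pairs"] = len(db)

        # ---- single-cell pipeline ---------------------------------------
        stage = "scrna"
        manifest.stamp(stage)
        g_filtered = scrna.filter_genes(raw, min_count=config.qc.min_count,
                                        min_cells=config.qc.min_cells)
        filtered = scrna.filter_cells(g_filtered,
                                      min_genes=config.qc.min_genes)
        logger.info("QC: %d/%d genes, %d/%d cells passed",
                    filtered.n_genes, raw.n_genes,
                    filtered.n_cells, raw.n_cells)
        nm = scrna.log_normalize(filtered,
                                 scale_factor=config.normalize.scale_factor)
        hvg = scrna.find_variable_genes(nm, n_bins=config.variable_genes.n_bins,
                                        z_cutoff=config.variable_genes.z_cutoff)
        genes = list(hvg.gene)
        if len(genes) < max(50, config.pca.n_pcs):
            logger.warning("only %d variable genes; using all genes for PCA",
                           len(genes))
            genes = list(nm.gene_ids)
        pca = scrna.run_pca(nm, genes, n_pcs=config.pca.n_pcs)
        js_cfg = scrna.JackstrawConfig(
            alpha=config.jackstraw.alpha,
            n_replicates=config.jackstraw.n_replicates,
            permuted_gene_fraction=config.jackstraw.permuted_gene_fraction,
            n_pcs_tested=config.jackstraw.n_pcs_tested,
            seed=_derive_seed(config.seed, "jackstraw"))
        sig_pcs, pc_p = scrna.jackstraw_select_pcs(nm, pca, js_cfg)
        n_use = max(sig_pcs) + 1 if sig_pcs else min(10, pca.n_pcs)
        if not sig_pcs:
            logger.warning("no PC significant at alpha=%g; falling back to "
                           "the first %d PCs", js_cfg.alpha, n_use)
        labels = scrna.cluster_cells(
            pca.embedding, n_pcs_used=n_use,
            resolution=config.cluster.resolution,
            k_neighbors=config.cluster.k_neighbors,
            seed=_derive_seed(config.seed, "cluster"),
            cell_ids=nm.cell_ids)
        markers = scrna.find_markers(
            nm, labels, logfc_threshold=config.markers.logfc_threshold)

        mio.write_expression(filtered, out / "filtered_counts", format="mtx")
        mio.write_normalized(nm, out / "normalized")
        hvg.to_csv(out / "variable_genes.csv", index=False)
        pd.DataFrame({"pc": np.arange(len(pc_p)), "p_value": pc_p,
                      "significant": [i in sig_pcs for i in range(len(pc_p))]}
                     ).to_csv(out / "jackstraw.csv", index=False)
        mio.write_labels(labels, out / "cluster_labels.tsv")
        markers.to_csv(out / "markers.csv", index=False)
        qc_report = {
            "genes_before": raw.n_genes, "genes_after": filtered.n_genes,
            "cells_before": raw.n_cells, "cells_after": filtered.n_cells,
            "n_variable_genes": len(hvg), "n_significant_pcs": len(sig_pcs),
            "n_clusters": labels.n_clusters,
        }
        (out / "qc_report.json").write_text(json.dumps(qc_report, indent=2))
        manifest.record_counts.update({
            "scrna.genes_after_qc": filtered.n_genes,
            "scrna.cells_after_qc": filtered.n_cells,
            "scrna.variable_genes": len(hvg),
            "scrna.significant_pcs": len(sig_pcs),
            "scrna.clusters": labels.n_clusters,
            "scrna.markers": len(markers),
        })

        # ---- connectivity screen ----------------------------------------
        stage = "connectivity"
        manifest.stamp(stage)
        labels_file = mio.read_labels(out / "cluster_labels.tsv")
        profile = conn.build_cluster_profile(nm, labels_file)
        calls = conn.call_presence(
            profile,
            min_detection_fraction=config.presence.min_detection_fraction,
            min_mean=config.presence.min_mean)
        senders = (config.connectivity.senders
                   if config.connectivity.senders is not None
                   else profile.clusters)
        receivers = (config.connectivity.receivers
                     if config.connectivity.receivers is not None
                     else profile.clusters)
        imap = conn.count_interactions(calls, db, senders, receivers)
        ranked = conn.score_pairings(profile, db, senders, receivers,
                                     top_k=config.connectivity.top_k)
        conn.render_interaction_heatmap(imap, out / "interactions.png")
        ranked.to_csv(out / "top_pairings.csv", index=False)
        contrib = pd.DataFrame(
            [{"sender": s, "receiver": r, "ligand": l, "receptor": rec}
             for (s, r), pairs in sorted(imap.contributing.items())
             for l, rec in pairs])
        contrib.to_csv(out / "contributing_pairs.csv", index=False)
        pd.DataFrame(imap.skipped_pairs, columns=["ligand", "receptor"]
                     ).to_csv(out / "skipped_pairs.csv", index=False)
        manifest.record_counts["connectivity.total_interactions"] = int(
            imap.counts.values.sum())
        manifest.record_counts["connectivity.skipped_pairs"] = len(
            imap.skipped_pairs)

        # ---- contraction quantification ---------------------------------
        stage = "moveheat"
        manifest.stamp(stage)
        mcfg = config.moveheat
        score_rows = []
        scores_by_group: dict[str, list[mh.ContractionScore]] = {}
        for group, amplitude in mcfg.group_amplitudes.items():
            scores_by_group[group] = []
            for rep in range(mcfg.replicates_per_group):
                vparams = VideoSimParams(
                    n_frames=mcfg.n_frames, height=mcfg.frame_size,
                    width=mcfg.frame_size, base_radius=mcfg.base_radius,
                    amplitude=amplitude, period=mcfg.period,
                    noise_sigma=mcfg.noise_sigma,
                    seed=_derive_seed(config.seed, f"video:{group}:{rep}"))
                stack = generate_contraction_video(vparams)
                stack.source_id = f"{group}_{rep}"
                mio.write_video_tiff(stack, out / f"video_{group}_{rep}.tiff")
                heat = mh.compute_heat_map(stack, lag=mcfg.lag)
                mh.render_heat_image(heat, out / f"heat_{group}_{rep}.png")
                sc = mh.contraction_score(heat, group_label=group)
                scores_by_group[group].append(sc)
                score_rows.append({
                    "source_id": sc.source_id, "group": group,
                    "lag": mcfg.lag, "n_pairs": heat.n_pairs,
                    "score": sc.score})
        scores_df = pd.DataFrame(score_rows)
        scores_df.to_csv(out / "contraction_scores.csv", index=False)
        anova = mh.compare_groups(scores_by_group)
        anova.to_csv(out / "contraction_anova.csv", index=False)
        manifest.record_counts["moveheat.videos"] = len(score_rows)

        # ---- manifest ----------------------------------------------------
        stage = "manifest"
        manifest.stamp(stage)
        for path in sorted(out.rglob("*")):
            if path.is_file() and path.name != "manifest.json":
                manifest.add_file(path, out)
        manifest.write(out / "manifest.json")
    except Exception as exc:  # noqa: BLE001 - stage name is the useful context
        raise StageError(stage, exc) from exc
    return manifest
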