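"""Pipeline configuration: typed sections, YAML round-trip, strict keys.

Unknown keys are rejected on load so a typo cannot silently fall back to a
default threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "default_synthetic_config"]


def _from_dict(cls, data: dict[str, Any]):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} key(s): {sorted(unknown)}; "
            f"valid keys: {sorted(known)}"
        )
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        section_cls = None
        if f.default_factory is not dataclasses.MISSING:
            default = f.default_factory()
            if dataclasses.is_dataclass(default):
                section_cls = type(default)
        if section_cls is not None and isinstance(value, dict):
            kwargs[name] = _from_dict(section_cls, value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


@dataclass
class SynthSection:
    n_clusters: int = 4
    cells_per_cluster: int = 100
    n_genes: int = 300
    marker_genes_per_cluster: int = 10
    marker_log_fold_change: float = 1.0
    nb_dispersion: float = 0.1
    baseline_mean: float = 5.0
    n_silent_genes: int = 20
    planted_lr_channels: list = field(default_factory=lambda: [
        ["LIG0", "REC0", 0, 1], ["LIG1", "REC1", 2, 1]])
    n_decoy_pairs: int = 5


@dataclass
class QCSection:
    min_count: int = 2        # a gene needs a count >= this ...
    min_cells: int = 3        # ... in at least this many cells
    min_genes: int = 1000     # a cell must express at least this many genes


@dataclass
class NormalizeSection:
    scale_factor: float = 10000.0


@dataclass
class VariableGenesSection:
    n_bins: int = 20
    z_cutoff: float = 1.0


@dataclass
class PCASection:
    n_pcs: int = 20


@dataclass
class JackstrawSection:
    alpha: float = 6.02e-5
    n_replicates: int = 100
    permuted_gene_fraction: float = 0.01
    n_pcs_tested: int = 20


@dataclass
class ClusterSection:
    resolution: float = 0.8
    k_neighbors: int = 20


@dataclass
class MarkersSection:
    logfc_threshold: float = 0.25


@dataclass
class PresenceSection:
    min_detection_fraction: float = 0.1
    min_mean: float = 0.25


@dataclass
class ConnectivitySection:
    senders: list | None = None    # None: every cluster
    receivers: list | None = None
    top_k: int = 50


@dataclass
class MoveheatSection:
    lag: int = 4
    n_frames: int = 60
    frame_size: int = 64
    base_radius: float = 20.0
    period: float = 20.0
    noise_sigma: float = 0.01
    # contraction amplitude per experimental group, replicated videos each
    group_amplitudes: dict = field(default_factory=lambda: {
        "MR": 0.20, "TM": 0.10, "TR": 0.08, "M": 0.02, "R": 0.02})
    replicates_per_group: int = 3


@dataclass
class PipelineConfig:
    """All stage parameters, a global seed and the output directory."""

    seed: int = 0
    out_dir: str = "runs/latest"
    synth: SynthSection = field(default_factory=SynthSection)
    qc: QCSection = field(default_factory=QCSection)
    normalize: NormalizeSection = field(default_factory=NormalizeSection)
    variable_genes: VariableGenesSection = field(
        default_factory=VariableGenesSection)
    pca: PCASection = field(default_factory=PCASection)
    jackstraw: JackstrawSection = field(default_factory=JackstrawSection)
    cluster: ClusterSection = field(default_factory=ClusterSection)
    markers: MarkersSection = field(default_factory=MarkersSection)
    presence: PresenceSection = field(default_factory=PresenceSection)
    connectivity: ConnectivitySection = field(
        default_factory=ConnectivitySection)
    moveheat: MoveheatSection = field(default_factory=MoveheatSection)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        return _from_dict(cls, data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})


def default_synthetic_config(seed: int = 0,
                             out_dir: str = "runs/synthetic") -> PipelineConfig:
    """Config for a self-contained synthetic run.

    Identical to the library defaults except that the cell filter is scaled
    to the synthetic gene universe (50 of ~300 genes, mirroring the
    1000-genes-of-~20k rule used on real data).
    """
    cfg = PipelineConfig(seed=seed, out_dir=out_dir)
    cfg.qc.min_genes = 50
    return cfg
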