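"""Readers and writers for the pipeline's on-disk formats.

Expression matrices travel as MatrixMarket triplets (matrix.mtx +
genes.tsv + barcodes.tsv, the 10x-style layout) or dense CSV (genes as
rows); cluster labels as a two-column TSV; videos as multi-page 8-bit
grayscale TIFF; simulation ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import io as scipy_io
from scipy import sparse

from .moveheat import FrameStack
from .scrna import ClusterLabels, CountMatrix, NormalizedMatrix
from .synthetic import LRChannel, PlantedTruth

__all__ = [
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "write_video_tiff",
    "write_normalized",
    "read_normalized",
    "write_truth",
    "read_truth",
]


class FormatError(ValueError):
    """Raised when an input file fails structural validation."""


def _read_id_file(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            token = line.rstrip("\n").split("\t")[0]
            if not token:
                raise FormatError(f"{path}:{lineno}: empty identifier")
            ids.append(token)
    return ids


def read_expression(path: str | Path, format: str = "mtx") -> CountMatrix:
    """Read a raw count matrix.

    ``format='mtx'``: ``path`` is a directory containing matrix.mtx,
    genes.tsv and barcodes.tsv.  ``format='csv'``: ``path`` is a dense CSV
    with genes as rows (index) and cells as columns.  Counts must be
    integers; mismatched dimensions are rejected with a FormatError.
    """
    path = Path(path)
    if format == "mtx":
        mtx = scipy_io.mmread(path / "matrix.mtx")
        genes = _read_id_file(path / "genes.tsv")
        cells = _read_id_file(path / "barcodes.tsv")
        arr = np.asarray(mtx.todense() if sparse.issparse(mtx) else mtx)
        if arr.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix.mtx declares {arr.shape[0]} x {arr.shape[1]} but id "
                f"files list {len(genes)} genes and {len(cells)} cells"
            )
    elif format == "csv":
        df = pd.read_csv(path, index_col=0)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
        arr = df.to_numpy()
    else:
        raise ValueError(f"unknown expression format {format!r}")
    rounded = np.rint(arr)
    if not np.allclose(arr, rounded, atol=1e-9):
        bad = np.argwhere(~np.isclose(arr, rounded, atol=1e-9))[0]
        raise FormatError(
            f"non-integer count at gene {genes[bad[0]]!r}, "
            f"cell {cells[bad[1]]!r}: {arr[tuple(bad)]}"
        )
    return CountMatrix(counts=rounded.astype(np.int64), gene_ids=genes,
                       cell_ids=cells, provenance=str(path))


def write_expression(m: CountMatrix, path: str | Path,
                     format: str = "mtx") -> Path:
    """Write a count matrix in the layout :func:`read_expression` expects."""
    path = Path(path)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy_io.mmwrite(path / "matrix.mtx",
                         sparse.coo_matrix(m.counts), field="integer")
        (path / "genes.tsv").write_text(
            "".join(f"{g}\n" for g in m.gene_ids))
        (path / "barcodes.tsv").write_text(
            "".join(f"{c}\n" for c in m.cell_ids))
    elif format == "csv":
        pd.DataFrame(m.counts, index=m.gene_ids,
                     columns=m.cell_ids).to_csv(path)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    return path


def write_normalized(nm: NormalizedMatrix, path: str | Path) -> Path:
    """Write a normalized matrix as a real-valued MatrixMarket directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(path / "matrix.mtx", sparse.coo_matrix(nm.values),
                     field="real", precision=12)
    (path / "genes.tsv").write_text("".join(f"{g}\n" for g in nm.gene_ids))
    (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in nm.cell_ids))
    (path / "normalization.json").write_text(json.dumps(
        {"scale_factor": nm.scale_factor, "log_base": nm.log_base}))
    return path


def read_normalized(path: str | Path) -> NormalizedMatrix:
    path = Path(path)
    mtx = scipy_io.mmread(path / "matrix.mtx")
    genes = _read_id_file(path / "genes.tsv")
    cells = _read_id_file(path / "barcodes.tsv")
    arr = np.asarray(mtx.todense() if sparse.issparse(mtx) else mtx,
                     dtype=float)
    if arr.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix.mtx declares {arr.shape} but id files list "
            f"{len(genes)} genes and {len(cells)} cells"
        )
    meta_path = path / "normalization.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return NormalizedMatrix(values=arr, gene_ids=genes, cell_ids=cells,
                            scale_factor=meta.get("scale_factor", 10000.0),
                            log_base=meta.get("log_base", "e"))


def write_labels(labels: ClusterLabels | pd.Series, path: str | Path) -> Path:
    path = Path(path)
    s = labels.assignments if isinstance(labels, ClusterLabels) else pd.Series(labels)
    s.rename("cluster").rename_axis("cell_id").to_csv(path, sep="\t")
    return path


def read_labels(path: str | Path) -> ClusterLabels:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["cell_id", "cluster"]:
        raise FormatError(
            f"labels file must have columns cell_id, cluster; "
            f"got {list(df.columns)}"
        )
    s = pd.Series(df["cluster"].to_numpy(), index=df["cell_id"].astype(str))
    return ClusterLabels(assignments=s)


def write_video_tiff(stack: FrameStack, path: str | Path) -> Path:
    """Write a frame stack as a multi-page 8-bit grayscale TIFF."""
    path = Path(path)
    frames8 = np.round(stack.frames * 255.0).astype(np.uint8)
    tifffile.imwrite(path, frames8)
    return path


def write_truth(truth: PlantedTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "marker_genes": {str(k): v for k, v in truth.marker_genes.items()},
        "channels": [
            {"ligand": c.ligand, "receptor": c.receptor,
             "sender": c.sender, "receiver": c.receiver}
            for c in truth.channels
        ],
        "true_means": truth.true_means.to_dict(orient="split"),
        "decoy_pool": truth.decoy_pool,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_truth(path: str | Path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text())
    tm = payload["true_means"]
    return PlantedTruth(
        marker_genes={int(k): v for k, v in payload["marker_genes"].items()},
        channels=[LRChannel(**c) for c in payload["channels"]],
        true_means=pd.DataFrame(tm["data"], index=tm["index"],
                                columns=tm["columns"]),
        decoy_pool=payload["decoy_pool"],
    )
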