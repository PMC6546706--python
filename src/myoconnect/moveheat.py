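"""Moveheat: frame-differencing quantification of organoid contraction.

A contraction video is reduced to a per-pixel "change heat" map: the mean
absolute grayscale difference between frames a fixed lag apart (default 4
frames), averaged over all valid frame pairs.  The spatial mean of the heat
map is a scalar contraction-intensity score, comparable across organoids
recorded at the same magnification and frame rate.  Groups of scores are
compared by one-way ANOVA.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import stats

__all__ = [
    "FrameStack",
    "HeatMap",
    "ContractionScore",
    "to_grayscale",
    "compute_heat_map",
    "contraction_score",
    "render_heat_image",
    "compare_groups",
    "read_video",
]

#: ITU-R BT.601 luminance weights used for RGB -> gray conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameStack:
    """Ordered grayscale frames of one video, intensities in [0, 1].

    Parameters
    ----------
    frames
        Array of shape (T, H, W) with values in [0, 1].
    frame_interval
        Optional time between frames, seconds (metadata only).
    source_id
        Identifier of the originating video.
    """

    frames: np.ndarray
    frame_interval: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a T x H x W array, got shape {self.frames.shape}"
            )
        if self.frames.size and (self.frames.min() < 0 or self.frames.max() > 1):
            raise ValueError("frame intensities must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class HeatMap:
    """Per-pixel mean absolute lag-difference ("change heat") of a video."""

    heat: np.ndarray
    lag: int
    n_pairs: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.heat = np.asarray(self.heat, dtype=float)
        if self.heat.ndim != 2:
            raise ValueError("heat must be a 2-D array")


@dataclass
class ContractionScore:
    """Scalar contraction intensity: spatial mean of heat over a mask."""

    score: float
    mask_area: int
    group_label: str = ""
    source_id: str = ""


class InsufficientFramesError(ValueError):
    """Raised when a video is too short for the requested lag."""


def to_grayscale(frames: np.ndarray, source_id: str = "",
                 frame_interval: float | None = None) -> FrameStack:
    """Convert a color frame stack to grayscale luminance.

    Accepts (T, H, W) grayscale (passed through), or (T, H, W, 3) RGB
    combined with BT.601 weights 0.299 R + 0.587 G + 0.114 B.  8-bit and
    16-bit integer inputs are rescaled to [0, 1].
    """
    arr = np.asarray(frames)
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(float) / 65535.0
    else:
        arr = arr.astype(float)
    if arr.ndim == 3:
        gray = arr
    elif arr.ndim == 4 and arr.shape[-1] == 3:
        gray = arr @ LUMA_WEIGHTS
    else:
        raise ValueError(
            f"expected (T, H, W) or (T, H, W, 3) stack, got shape {arr.shape}"
        )
    return FrameStack(frames=np.clip(gray, 0.0, 1.0), source_id=source_id,
                      frame_interval=frame_interval)


def compute_heat_map(stack: FrameStack, lag: int = 4, *,
                     squared: bool = False, sliding: bool = True) -> HeatMap:
    """Compute the change-heat map of a video.

    heat(x, y) = mean over valid pairs of |I(t + lag, x, y) - I(t, x, y)|.

    Parameters
    ----------
    stack
        Grayscale frame stack, T >= lag + 1.
    lag
        Frame separation of each differenced pair (default 4).
    squared
        If True use squared differences instead of absolute (sensitivity
        studies; the score is then no longer bounded by 1 homogeneous).
    sliding
        If True (default) use every pair (t, t + lag); if False use disjoint
        pairs (0, lag), (2*lag, 3*lag), ... only.

    Raises
    ------
    InsufficientFramesError
        If T <= lag.
    """
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    T = stack.n_frames
    if T <= lag:
        raise InsufficientFramesError(
            f"need more than lag={lag} frames, video has T={T}"
        )
    frames = stack.frames
    if sliding:
        diffs = frames[lag:] - frames[:-lag]
    else:
        starts = np.arange(0, T - lag, 2 * lag)
        diffs = frames[starts + lag] - frames[starts]
    mag = diffs ** 2 if squared else np.abs(diffs)
    # canonical accumulation (ascending, strictly sequential): the per-pixel
    # mean then depends only on the multiset of differences, so reversing the
    # frame order gives bit-identical heat
    mag.sort(axis=0)
    acc = np.zeros_like(mag[0])
    for layer in mag:
        acc += layer
    heat = acc / mag.shape[0]
    return HeatMap(heat=heat, lag=lag, n_pairs=diffs.shape[0],
                   source_id=stack.source_id)


def contraction_score(heat: HeatMap, mask: np.ndarray | None = None,
                      group_label: str = "") -> ContractionScore:
    """Reduce a heat map to a scalar score: mean heat over a region.

    With no mask the whole frame is averaged.  The mask, if given, must
    match the heat-map shape and select at least one pixel.
    """
    h = heat.heat
    if mask is None:
        # exactly rounded sum: the score is invariant to pixel ordering
        score = math.fsum(h.ravel()) / h.size
        area = h.size
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != h.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match heat shape {h.shape}"
            )
        area = int(mask.sum())
        if area == 0:
            raise ValueError("mask selects no pixels")
        score = math.fsum(h[mask]) / area
    return ContractionScore(score=score, mask_area=area,
                            group_label=group_label, source_id=heat.source_id)


def render_heat_image(heat: HeatMap, out_path: str | Path) -> Path:
    """Write an 8-bit grayscale PNG of the heat map.

    Values are scaled linearly from [0, max(heat)] to [0, 255]; an all-zero
    map renders all black.  The scaling bounds are written to a sidecar
    ``<out_path>.json`` so the image remains quantitatively interpretable.
    """
    out_path = Path(out_path)
    hmax = float(heat.heat.max()) if heat.heat.size else 0.0
    if hmax > 0:
        img = np.round(heat.heat / hmax * 255.0).astype(np.uint8)
    else:
        img = np.zeros_like(heat.heat, dtype=np.uint8)
    iio.imwrite(out_path, img, extension=".png")
    sidecar = {
        "source_id": heat.source_id,
        "lag": heat.lag,
        "n_pairs": heat.n_pairs,
        "scale_min": 0.0,
        "scale_max": hmax,
    }
    out_path.with_suffix(out_path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))
    return out_path


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    scores: Mapping[str, Sequence[ContractionScore | float]],
) -> pd.DataFrame:
    """One-way ANOVA across groups of contraction scores.

    Returns a table with one row per group (mean, sd, n) plus the overall
    F statistic, p-value and a significance star code (* p<0.05, ** p<0.01,
    *** p<0.001).
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 groups to compare")
    values: dict[str, np.ndarray] = {}
    for label, group in scores.items():
        vals = np.array(
            [s.score if isinstance(s, ContractionScore) else float(s)
             for s in group]
        )
        if vals.size < 2:
            raise ValueError(
                f"group {label!r} has {vals.size} observation(s); need >= 2"
            )
        values[label] = vals
    f_stat, p_val = stats.f_oneway(*values.values())
    rows = [
        {
            "group": label,
            "n": v.size,
            "mean": v.mean(),
            "sd": v.std(ddof=1),
            "F": f_stat,
            "p_value": p_val,
            "significance": _stars(p_val),
        }
        for label, v in values.items()
    ]
    return pd.DataFrame(rows)


def read_video(path: str | Path, source_id: str | None = None) -> FrameStack:
    """Read a video file into a grayscale FrameStack.

    Multi-page TIFF is read with tifffile; other containers (AVI/MP4/GIF)
    are decoded by imageio.  Integer intensities are rescaled to [0, 1] and
    color frames converted to luminance.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:  # single frame
        arr = arr[None]
    return to_grayscale(arr, source_id=source_id or path.stem)
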