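"""Anatomical quantification: axon fluorescence by layer and rabies input maps.

Covers the three image/count analyses: integrated fluorescence intensity
inside hand-drawn layer ROIs, the EC_L5 : EC_L2/3 intensity ratio per
animal, pia-anchored depth profiles of axonal fluorescence averaged along
the dorsoventral axis, and percentage input contributions from monosynaptic
rabies presynaptic cell counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.path import Path

__all__ = [
    "LayerROI",
    "DepthProfile",
    "InputCountTable",
    "integrate_roi",
    "layer_intensity_ratio",
    "depth_profile",
    "input_contribution",
]


@dataclass
class LayerROI:
    """A polygonal ROI over one cortical layer of one slice."""

    slice_id: str
    layer: str  # "EC_L2/3" | "EC_L5"
    polygon: np.ndarray  # (n_vertices, 2) pixel coordinates (col, row)
    integrated_intensity: float | None = None

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[0] < 3 or self.polygon.shape[1] != 2:
            raise ValueError("ROI polygon needs at least 3 (x, y) vertices")


@dataclass
class DepthProfile:
    """Normalized fluorescence vs. distance from the pia (um)."""

    depth_um: np.ndarray
    intensity: np.ndarray  # max-normalized to 1

    def __post_init__(self) -> None:
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.depth_um) <= 0):
            raise ValueError("depth grid must be strictly increasing")


@dataclass
class InputCountTable:
    """GFP+ presynaptic cell counts per brain region for one animal."""

    counts: dict  # region -> non-negative int
    starter_region: str | None = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("cell counts must be >= 0")


def integrate_roi(image: np.ndarray, polygon) -> float:
    """Sum of pixel values whose centers fall inside the polygon.

    ``polygon`` is an (n, 2) array of (x=column, y=row) vertices; pixel
    centers sit at integer coordinates.
    """
    polygon = np.asarray(polygon, dtype=float)
    if polygon.ndim != 2 or polygon.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    image = np.asarray(image, dtype=float)
    if polygon[:, 0].min() < -0.5 or polygon[:, 1].min() < -0.5 \
            or polygon[:, 0].max() > image.shape[1] - 0.5 \
            or polygon[:, 1].max() > image.shape[0] - 0.5:
        raise ValueError("polygon extends outside the image")

    # restrict the membership test to the polygon's bounding box
    c0 = max(int(np.floor(polygon[:, 0].min())), 0)
    c1 = min(int(np.ceil(polygon[:, 0].max())) + 1, image.shape[1])
    r0 = max(int(np.floor(polygon[:, 1].min())), 0)
    r1 = min(int(np.ceil(polygon[:, 1].max())) + 1, image.shape[0])
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    pts = np.column_stack([cols.ravel(), rows.ravel()])
    inside = Path(polygon).contains_points(pts)
    return float(image[r0:r1, c0:c1].ravel()[inside].sum())


def layer_intensity_ratio(rois: list[LayerROI],
                          deep: str = "EC_L5",
                          superficial: str = "EC_L2/3") -> float:
    """EC_L5 : EC_L2/3 ratio of mean integrated intensity across slices."""
    deep_vals = [r.integrated_intensity for r in rois if r.layer == deep]
    sup_vals = [r.integrated_intensity for r in rois if r.layer == superficial]
    if not deep_vals or not sup_vals:
        raise ValueError("need at least one measured ROI per layer")
    if any(v is None for v in deep_vals + sup_vals):
        raise ValueError("all ROIs must carry an integrated_intensity")
    sup_mean = float(np.mean(sup_vals))
    if sup_mean == 0:
        raise ZeroDivisionError("superficial-layer mean intensity is zero")
    return float(np.mean(deep_vals)) / sup_mean


def depth_profile(profiles: list[tuple[np.ndarray, np.ndarray]],
                  grid_step: float = 5.0) -> DepthProfile:
    """Average per-slice line profiles onto a common depth grid.

    Each profile is ``(depth_um, intensity)`` starting at the pia.  Profiles
    are linearly resampled onto a grid of ``grid_step`` um spanning the
    depth range common to all slices, averaged, and max-normalized to 1.
    """
    if not profiles:
        raise ValueError("need at least one line profile")
    cleaned = []
    for d, v in profiles:
        d = np.asarray(d, dtype=float)
        v = np.asarray(v, dtype=float)
        if d.size == 0 or d.size != v.size:
            raise ValueError("profiles must be non-empty (depth, value) pairs")
        cleaned.append((d, v))
    lo = max(d[0] for d, _ in cleaned)
    hi = min(d[-1] for d, _ in cleaned)
    if hi <= lo:
        raise ValueError("profiles share no common depth range")
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    mean = np.mean([np.interp(grid, d, v) for d, v in cleaned], axis=0)
    peak = mean.max()
    if peak <= 0:
        raise ValueError("profile has no positive signal to normalize")
    return DepthProfile(depth_um=grid, intensity=mean / peak)


def input_contribution(table: InputCountTable,
                       exclude_starter_region: bool = False) -> pd.DataFrame:
    """Percentage of presynaptic cells per input region.

    ``percent = 100 * count / total``; percentages sum to 100.  Starter
    cells themselves are never in the counts; ``exclude_starter_region``
    additionally drops local cells of the starter region from the
    denominator.
    """
    counts = dict(table.counts)
    if exclude_starter_region and table.starter_region in counts:
        counts.pop(table.starter_region)
    if not counts:
        raise ValueError("input table is empty")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total presynaptic count must be > 0")
    df = pd.DataFrame(
        {"region": list(counts), "count": list(counts.values())}
    )
    df["percent"] = 100.0 * df["count"] / total
    return df.sort_values("percent", ascending=False, ignore_index=True)
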