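"""Apical-basal quantification of per-cell signal from segmentation ROI tables.

The ventricular surface (VS) is modelled as a circle through three manually
picked points. Each segmented cell's distance from the VS is expressed in
units of the average cell diameter (equivalent-circle diameter from ROI
area). Per channel and image, signals at or below a background quantile
(default 0.25) are zeroed, replicates are mean-normalized, and trends along
the distance axis are summarized by a centred sliding mean (window 12).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

BACKGROUND_QUANTILE = 0.25
SMOOTHING_WINDOW = 12

ROI_COLUMNS = ("roi_id", "x", "y", "area", "image", "replicate")


@dataclass(frozen=True)
class VsCircle:
    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def fit_vs_circle(p1: Sequence[float], p2: Sequence[float],
                  p3: Sequence[float]) -> VsCircle:
    """Unique circle through three pairwise-distinct, non-collinear points."""
    pts = np.array([p1, p2, p3], dtype=float)
    if len({tuple(p) for p in pts}) < 3:
        raise ValueError("points must be pairwise distinct")
    # Solve |p - c|^2 = r^2 as a linear system in (cx, cy, r^2 - |c|^2).
    a = np.column_stack([2 * pts, np.ones(3)])
    b = (pts ** 2).sum(axis=1)
    if abs(np.linalg.det(a)) < 1e-9:
        raise ValueError("points are collinear: no unique circle")
    cx, cy, k = np.linalg.solve(a, b)
    r = float(np.sqrt(k + cx ** 2 + cy ** 2))
    return VsCircle(float(cx), float(cy), r)


def average_cell_diameter(rois: pd.DataFrame) -> float:
    """Mean equivalent-circle diameter, 2 sqrt(area / pi), over all ROIs."""
    areas = rois["area"].to_numpy(dtype=float)
    if np.all(areas <= 0):
        raise ValueError("all ROI areas are non-positive")
    return float(np.mean(2.0 * np.sqrt(areas / np.pi)))


def quantify_profile(
    rois: pd.DataFrame,
    circle: VsCircle,
    background_quantile: float = BACKGROUND_QUANTILE,
    channels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-cell VS distance (average-cell-diameter units) + filtered signals.

    Distance = (|centroid - centre| - radius) / average diameter; cells
    apical to the circle get negative distances and are kept, flagged by
    sign. Per channel and image, signals at or below the background quantile
    are set to 0 (not dropped), so cell counts agree across channels.
    """
    if len(rois) < 2:
        raise ValueError("need at least 2 cells")
    channels = list(channels) if channels is not None else [
        c for c in rois.columns if c.startswith("ch")]
    out = rois.copy()
    diam = average_cell_diameter(out)
    d = np.hypot(out["x"] - circle.cx, out["y"] - circle.cy) - circle.radius
    out["distance"] = d / diam
    for ch in channels:
        filtered = out[ch].astype(float).copy()
        for _, idx in out.groupby("image").groups.items():
            vals = filtered.loc[idx]
            cut = vals.quantile(background_quantile)
            filtered.loc[idx] = vals.where(vals > cut, 0.0)
        out[ch] = filtered
    return out.sort_values("distance").reset_index(drop=True)


def normalize_replicates(profile: pd.DataFrame,
                         channels: Sequence[str] | None = None) -> pd.DataFrame:
    """Divide each channel by its replicate mean so replicate means equal 1."""
    channels = list(channels) if channels is not None else [
        c for c in profile.columns if c.startswith("ch")]
    out = profile.copy()
    for ch in channels:
        means = out.groupby("replicate")[ch].transform("mean")
        if (means == 0).any():
            raise ValueError(f"channel {ch}: a replicate has zero mean signal")
        out[ch] = out[ch] / means
    return out


def smooth_profile(values: Sequence[float],
                   window: int = SMOOTHING_WINDOW) -> np.ndarray:
    """Centred sliding mean over a distance-ordered signal.

    The window shrinks at the boundaries, so the output has the same length
    as the input and window=1 is the identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def read_roi_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ROI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ROI table missing columns: {sorted(missing)}")
    if (df["area"] <= 0).any():
        raise ValueError("ROI areas must be positive")
    return df
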