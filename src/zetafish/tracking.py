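"""Video tracking: per-frame segmentation and two-view centroid fusion.

The fish is filmed by two orthogonal cameras (top and side). In each frame
it is segmented by background subtraction and thresholding and represented
by the intensity-weighted center of gravity of the largest segment. The top
view provides (x, y), the side view provides z; the shared x coordinate is
used as a cross-view consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .trajectory import Trajectory

__all__ = [
    "ViewCalibration",
    "Detection",
    "estimate_background",
    "segment_frame",
    "track_frames",
    "fuse_views",
]


@dataclass
class ViewCalibration:
    """Linear px <-> cm mapping for one camera view.

    Image columns map to the tank's x axis in both views; image rows map to
    y (top view) or z (side view), increasing with the coordinate:
    ``cm = (px - origin_px) / px_per_cm``.
    """

    view: str  # 'top' or 'side'
    px_per_cm: tuple[float, float]  # (columns per cm, rows per cm)
    origin_px: tuple[float, float]  # (col, row) of the tank origin

    def to_cm(self, centroid_px: tuple[float, float]) -> tuple[float, float]:
        c, r = centroid_px
        return (
            (c - self.origin_px[0]) / self.px_per_cm[0],
            (r - self.origin_px[1]) / self.px_per_cm[1],
        )

    def to_px(self, u_cm: float, v_cm: float) -> tuple[float, float]:
        return (
            self.origin_px[0] + u_cm * self.px_per_cm[0],
            self.origin_px[1] + v_cm * self.px_per_cm[1],
        )


@dataclass
class Detection:
    frame: int
    view: str
    centroid_px: tuple[float, float]  # (col, row)
    area_px: int
    valid: bool

    @classmethod
    def invalid(cls, frame: int, view: str) -> "Detection":
        return cls(frame, view, (np.nan, np.nan), 0, False)


def estimate_background(frames: Sequence[np.ndarray]) -> np.ndarray:
    """Median background over a stack of grayscale frames."""
    return np.median(np.asarray(frames, dtype=float), axis=0)


def segment_frame(
    frame: np.ndarray,
    background: np.ndarray,
    min_area_px: int = 20,
    threshold_floor: float = 10.0,
    frame_index: int = 0,
    view: str = "top",
) -> Detection:
    """Segment the fish in one frame and return its center of gravity.

    The background is subtracted, the difference thresholded (Otsu, floored
    at ``threshold_floor``), and the largest connected component with area
    >= ``min_area_px`` is reduced to its intensity-weighted centroid. A
    frame with no qualifying segment yields an invalid detection, never an
    exception.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background must have the same shape")
    diff = frame - background
    np.clip(diff, 0.0, None, out=diff)
    if diff.size == 0 or diff.max() <= threshold_floor:
        return Detection.invalid(frame_index, view)
    try:
        thr = max(float(threshold_otsu(diff)), threshold_floor)
    except ValueError:  # degenerate histogram
        thr = threshold_floor
    mask = diff > thr
    if not mask.any():
        return Detection.invalid(frame_index, view)
    labels = label(mask)
    best = None
    for region in regionprops(labels, intensity_image=diff):
        if region.area < min_area_px:
            continue
        if best is None or region.area > best.area:
            best = region
    if best is None:
        return Detection.invalid(frame_index, view)
    row, col = best.centroid_weighted
    return Detection(frame_index, view, (float(col), float(row)), int(best.area), True)


def track_frames(
    frames: Sequence[np.ndarray],
    background: np.ndarray | None = None,
    view: str = "top",
    min_area_px: int = 20,
    threshold_floor: float = 10.0,
) -> list[Detection]:
    """Segment every frame of one view against a (median) background."""
    if background is None:
        background = estimate_background(frames)
    return [
        segment_frame(f, background, min_area_px, threshold_floor, i, view)
        for i, f in enumerate(frames)
    ]


def _interp_gaps(vals: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate NaN runs; flag runs longer than ``max_gap``."""
    vals = vals.copy()
    n = len(vals)
    flagged = np.zeros(n, dtype=bool)
    isnan = np.isnan(vals)
    if isnan.all():
        raise ValueError("no valid detections to fuse")
    idx = np.arange(n)
    # flag long runs (and unbounded leading/trailing runs) before filling
    i = 0
    while i < n:
        if isnan[i]:
            j = i
            while j < n and isnan[j]:
                j += 1
            run = j - i
            if run > max_gap or i == 0 or j == n:
                flagged[i:j] = True
            i = j
        else:
            i += 1
    vals[isnan] = np.interp(idx[isnan], idx[~isnan], vals[~isnan])
    return vals, flagged


def fuse_views(
    top: Sequence[Detection],
    side: Sequence[Detection],
    calib: tuple[ViewCalibration, ViewCalibration],
    fps: float = 30.0,
    fish_id: str = "fish0",
    max_gap_frames: int = 10,
    x_consistency_cm: float = 0.5,
) -> Trajectory:
    """Fuse frame-aligned top/side detections into a 3D trajectory.

    x and y come from the top view and z from the side view; the side
    view's x is used only as a consistency check (frames disagreeing by
    more than ``x_consistency_cm`` are flagged and the top view trusted).
    Invalid-detection gaps are linearly interpolated; gaps longer than
    ``max_gap_frames`` are filled too but flagged frame by frame.
    """
    if len(top) != len(side):
        raise ValueError("top and side detection sequences must be frame-aligned")
    ctop, cside = calib
    n = len(top)
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    z = np.full(n, np.nan)
    x_side = np.full(n, np.nan)
    for i, (dt_, ds_) in enumerate(zip(top, side)):
        if dt_.valid:
            x[i], y[i] = ctop.to_cm(dt_.centroid_px)
        if ds_.valid:
            x_side[i], z[i] = cside.to_cm(ds_.centroid_px)
    flags = np.zeros(n, dtype=np.uint8)
    for arr in (x, y, z):
        filled, long_gap = _interp_gaps(arr, max_gap_frames)
        arr[:] = filled
        flags[long_gap] |= Trajectory.FLAG_LONG_GAP
    mismatch = np.abs(x - x_side) > x_consistency_cm
    mismatch &= ~np.isnan(x_side)
    flags[mismatch] |= Trajectory.FLAG_X_MISMATCH
    t = np.arange(n) / fps
    return Trajectory(fish_id=fish_id, fps=fps, t=t, pos=np.column_stack([x, y, z]), flags=flags)
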