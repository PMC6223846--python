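"""The six behavioral parameters extracted from a 3D trajectory.

(1) Speed      instantaneous swimming speed, cm/s (3D displacement between
               successive frames times the frame rate)
(2) Zlevel     relative position in the water column, 0 = bottom, 1 = surface
(3) Area       binary residence in the rectangular reward zone
(4) Surface    surface-sampling events: upward crossings of a z threshold
               (~70% of the water column) below the feeding-ring center
(5) Distance   3D distance to the opening of the inflow tube, cm
(6) Circling   stereotyped wall-following swimming, quantified per 1-s bin
               as the relative spectral power of the long-axis (x) position
               in a low-frequency band (0.029-0.146 Hz), estimated from a
               30-s Tukey-tapered window

All six are pure functions of (trajectory, geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import tukey

from .config import AnalysisParams, TankGeometry
from .trajectory import Trajectory

__all__ = [
    "PARAMETERS",
    "SIGN_INVERTED",
    "compute_speed",
    "compute_zlevel",
    "compute_area",
    "detect_surface_events",
    "compute_distance_to_inflow",
    "compute_circling",
    "ParameterPanel",
]

PARAMETERS = ["Speed", "Zlevel", "Area", "Surface", "Distance", "Circling"]

#: parameters whose appetitive direction is a decrease (sign of the
#: normalized score is inverted downstream so positive = more appetitive)
SIGN_INVERTED = frozenset({"Distance", "Circling"})


def compute_speed(traj: Trajectory) -> np.ndarray:
    """Instantaneous 3D swimming speed in cm/s, one value per frame.

    The first frame has no predecessor and is assigned the second frame's
    value so all parameter series stay frame-aligned.
    """
    if len(traj) < 2:
        raise ValueError("speed needs at least two frames")
    traj.check_uniform()
    disp = np.linalg.norm(np.diff(traj.pos, axis=0), axis=1)
    speed = np.empty(len(traj))
    speed[1:] = disp * traj.fps
    speed[0] = speed[1]
    return speed


def compute_zlevel(traj: Trajectory, geometry: TankGeometry) -> np.ndarray:
    """Relative height in the water column, clipped to [0, 1]."""
    return np.clip(traj.z / geometry.water_height_cm, 0.0, 1.0)


def compute_area(traj: Trajectory, geometry: TankGeometry) -> np.ndarray:
    """Binary reward-zone residence (closed rectangle boundaries)."""
    x0, y0, x1, y1 = geometry.reward_zone
    inside = (traj.x >= x0) & (traj.x <= x1) & (traj.y >= y0) & (traj.y <= y1)
    return inside.astype(float)


def detect_surface_events(traj: Trajectory, geometry: TankGeometry) -> np.ndarray:
    """Surface-sampling events as a per-frame 0/1 indicator.

    An event is an upward crossing of the z threshold while the fish is
    horizontally within the feeding ring; the indicator is 1 at the
    crossing frame. A new event requires z to first drop below the
    threshold again (hysteresis), so a single excursion counts once.
    """
    thr = geometry.surface_threshold_cm
    above = traj.z >= thr
    crossing = np.zeros(len(traj), dtype=bool)
    crossing[1:] = above[1:] & ~above[:-1]
    rx, ry = geometry.ring_center
    in_ring = (traj.x - rx) ** 2 + (traj.y - ry) ** 2 <= geometry.ring_radius_cm**2
    return (crossing & in_ring).astype(float)


def compute_distance_to_inflow(traj: Trajectory, geometry: TankGeometry) -> np.ndarray:
    """3D Euclidean distance to the inflow-tube opening, cm."""
    return np.linalg.norm(traj.pos - np.asarray(geometry.inflow_pos), axis=1)


def compute_circling(
    traj: Trajectory,
    band_hz: tuple[float, float] = (0.029, 0.146),
    window_s: float = 30.0,
    tukey_alpha: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative low-frequency power of the long-axis position, per 1-s bin.

    For each 1-s bin the 30-s x-position segment centered on the bin is
    mean-detrended, Tukey-tapered, and its periodogram integrated over
    ``band_hz``; the value is that band power divided by the total power
    excluding the DC bin, giving a number in [0, 1]. Bins near the edges
    use the nearest full window. A constant segment (no motion) is defined
    as 0.

    Returns ``(t_bins, values)`` with bin centers in seconds.
    """
    fps = traj.fps
    n = len(traj)
    win = int(round(window_s * fps))
    if n < win:
        raise ValueError("trajectory shorter than the spectral window")
    n_bins = int(np.floor(traj.t[-1]))
    if n_bins < 1:
        raise ValueError("trajectory shorter than one bin")
    centers = np.arange(n_bins) + 0.5
    starts = np.round(centers * fps).astype(int) - win // 2
    np.clip(starts, 0, n - win, out=starts)
    seg = traj.x[starts[:, None] + np.arange(win)[None, :]]
    seg = seg - seg.mean(axis=1, keepdims=True)
    seg *= tukey(win, tukey_alpha)[None, :]
    spec = np.abs(np.fft.rfft(seg, axis=1)) ** 2
    freqs = np.fft.rfftfreq(win, d=1.0 / fps)
    band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    total = spec[:, 1:].sum(axis=1)
    band_power = spec[:, band].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(total > 0, band_power / total, 0.0)
    return centers, rel


@dataclass
class ParameterPanel:
    """Per-fish panel of the six parameter time series.

    Five parameters are frame-aligned to the trajectory; Circling lives on
    its own 1-s bin grid. Each entry maps the parameter name to a
    ``(t_seconds, values)`` pair.
    """

    fish_id: str
    series: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_trajectory(
        cls,
        traj: Trajectory,
        geometry: TankGeometry,
        analysis: AnalysisParams | None = None,
    ) -> "ParameterPanel":
        analysis = analysis or AnalysisParams()
        t = traj.t
        series = {
            "Speed": (t, compute_speed(traj)),
            "Zlevel": (t, compute_zlevel(traj, geometry)),
            "Area": (t, compute_area(traj, geometry)),
            "Surface": (t, detect_surface_events(traj, geometry)),
            "Distance": (t, compute_distance_to_inflow(traj, geometry)),
        }
        tb, circ = compute_circling(
            traj,
            band_hz=analysis.band_hz,
            window_s=analysis.circling_window_s,
            tukey_alpha=analysis.tukey_alpha,
        )
        series["Circling"] = (tb, circ)
        return cls(fish_id=traj.fish_id, series=series)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: fish_id, frame, t_s, parameter, value."""
        parts = []
        for name in PARAMETERS:
            t, v = self.series[name]
            parts.append(
                pd.DataFrame(
                    {
                        "fish_id": self.fish_id,
                        "frame": np.arange(len(t)),
                        "t_s": t,
                        "parameter": name,
                        "value": v,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParameterPanel":
        fish_ids = df["fish_id"].unique()
        if len(fish_ids) != 1:
            raise ValueError("panel table must contain a single fish")
        series = {}
        for name, grp in df.groupby("parameter"):
            grp = grp.sort_values("frame")
            series[name] = (grp["t_s"].to_numpy(float), grp["value"].to_numpy(float))
        missing = [p for p in PARAMETERS if p not in series]
        if missing:
            raise ValueError(f"panel missing parameters: {missing}")
        return cls(fish_id=str(fish_ids[0]), series=series)
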