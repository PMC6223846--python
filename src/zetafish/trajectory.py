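"""3D trajectory container and plain-text (CSV) interchange."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "TRAJECTORY_COLUMNS"]

TRAJECTORY_COLUMNS = ["fish_id", "frame", "t_s", "x_cm", "y_cm", "z_cm"]


@dataclass
class Trajectory:
    """Per-fish time series of 3D position sampled at a fixed frame rate.

    ``pos`` is an (n, 3) array of (x, y, z) in cm; ``t`` is seconds.
    ``flags`` optionally carries per-frame quality annotations produced by
    tracking (0 = clean).
    """

    fish_id: str
    fps: float
    t: np.ndarray
    pos: np.ndarray
    flags: np.ndarray | None = field(default=None, repr=False)

    FLAG_LONG_GAP = 1
    FLAG_X_MISMATCH = 2

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.ndim != 2 or self.pos.shape[1] != 3:
            raise ValueError("pos must be an (n, 3) array")
        if self.t.shape[0] != self.pos.shape[0]:
            raise ValueError("t and pos must have the same length")

    def __len__(self) -> int:
        return self.pos.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.pos[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.pos[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.pos[:, 2]

    def check_uniform(self, rtol: float = 1e-6) -> float:
        """Return the frame interval; error if timestamps are not uniform."""
        dt = np.diff(self.t)
        if len(dt) == 0:
            return 1.0 / self.fps
        if np.ptp(dt) > rtol * dt.mean():
            raise ValueError("trajectory timestamps are not uniformly spaced")
        return float(dt.mean())

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame(
            {
                "fish_id": np.repeat(self.fish_id, n),
                "frame": np.arange(n),
                "t_s": self.t,
                "x_cm": self.pos[:, 0],
                "y_cm": self.pos[:, 1],
                "z_cm": self.pos[:, 2],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fps: float | None = None) -> "Trajectory":
        missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns: {missing}")
        df = df.sort_values("frame")
        fish_ids = df["fish_id"].unique()
        if len(fish_ids) != 1:
            raise ValueError("trajectory table must contain a single fish")
        t = df["t_s"].to_numpy(float)
        if fps is None:
            dt = np.diff(t)
            fps = 1.0 / float(dt.mean()) if len(dt) else 30.0
        pos = df[["x_cm", "y_cm", "z_cm"]].to_numpy(float)
        return cls(fish_id=str(fish_ids[0]), fps=fps, t=t, pos=pos)

    @classmethod
    def read_csv(cls, path, fps: float | None = None) -> "Trajectory":
        return cls.from_dataframe(pd.read_csv(path), fps=fps)
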