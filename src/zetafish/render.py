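"""Render synthetic two-view grayscale video from a 3D trajectory.

Each frame pair shows the fish as a single bright elliptical (Gaussian)
blob on a dark background, positioned so that the blob's intensity
centroid maps back to the 3D position under the declared px <-> cm
calibration. The top view encodes (x, y), the side view (x, z). Realistic
fish appearance is deliberately out of scope.
"""

from __future__ import annotations

import numpy as np

from .config import TankGeometry
from .tracking import ViewCalibration
from .trajectory import Trajectory

__all__ = ["render_views"]

_PAD_PX = 14
_BACKGROUND = 8.0
_PEAK = 200.0


def _draw_blob(img: np.ndarray, c: float, r: float, sig_c: float, sig_r: float) -> None:
    h, w = img.shape
    rad_c = int(np.ceil(4 * sig_c))
    rad_r = int(np.ceil(4 * sig_r))
    c0, c1 = max(0, int(c) - rad_c), min(w, int(c) + rad_c + 1)
    r0, r1 = max(0, int(r) - rad_r), min(h, int(r) + rad_r + 1)
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    gc = np.exp(-0.5 * ((cols - c) / sig_c) ** 2)
    gr = np.exp(-0.5 * ((rows - r) / sig_r) ** 2)
    img[r0:r1, c0:c1] += _PEAK * np.outer(gr, gc)


def render_views(
    traj: Trajectory,
    geometry: TankGeometry,
    image_size_px: tuple[int, int] = (240, 120),
    blob_sigma_cm: tuple[float, float] = (0.45, 0.20),
) -> tuple[np.ndarray, np.ndarray, tuple[ViewCalibration, ViewCalibration]]:
    """Render paired top/side frames for every trajectory sample.

    Returns uint8 stacks of shape (n, height, width) for the two views and
    the calibrations that map pixel centroids back to cm. Both views share
    the same x (column) scale. A blob larger than the image is rejected.
    """
    w_px, h_px = image_size_px
    x, y, z = traj.x, traj.y, traj.z
    if (x.min() < 0 or y.min() < 0 or z.min() < 0
            or x.max() > geometry.length_cm or y.max() > geometry.width_cm
            or z.max() > geometry.water_height_cm):
        raise ValueError("trajectory extends outside the tank bounds")
    ppc = min(
        (w_px - 2 * _PAD_PX) / geometry.length_cm,
        (h_px - 2 * _PAD_PX) / geometry.width_cm,
        (h_px - 2 * _PAD_PX) / geometry.water_height_cm,
    )
    if ppc <= 0:
        raise ValueError("image too small for the tank footprint")
    sig_c, sig_r = blob_sigma_cm[0] * ppc, blob_sigma_cm[1] * ppc
    if 6 * sig_c > w_px - 2 * _PAD_PX or 6 * sig_r > h_px - 2 * _PAD_PX:
        raise ValueError("fish blob larger than the drawable image area")
    calib_top = ViewCalibration("top", (ppc, ppc), (float(_PAD_PX), float(_PAD_PX)))
    calib_side = ViewCalibration("side", (ppc, ppc), (float(_PAD_PX), float(_PAD_PX)))
    n = len(traj)
    top = np.empty((n, h_px, w_px), dtype=np.uint8)
    side = np.empty((n, h_px, w_px), dtype=np.uint8)
    buf = np.empty((h_px, w_px), dtype=float)
    for i in range(n):
        buf.fill(_BACKGROUND)
        c, r = calib_top.to_px(x[i], y[i])
        _draw_blob(buf, c, r, sig_c, sig_r)
        np.clip(buf, 0, 255, out=buf)
        top[i] = buf.astype(np.uint8)
        buf.fill(_BACKGROUND)
        c, r = calib_side.to_px(x[i], z[i])
        _draw_blob(buf, c, r, sig_c, sig_r)
        np.clip(buf, 0, 255, out=buf)
        side[i] = buf.astype(np.uint8)
    return top, side, (calib_top, calib_side)
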