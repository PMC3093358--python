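"""Geometry helpers shared by the rasterizer and midline extraction.

Coordinate convention: plate coordinates are millimetres with y increasing
upward.  An image frame of shape (H, W) with pixel size ``px`` and origin
offset ``(off_x, off_y)`` (mm position of the bottom-left frame corner) maps
pixel (row, col) centers to mm as

    x_mm = off_x + (col + 0.5) * px
    y_mm = off_y + (H - row - 0.5) * px

so row 0 is the top of the frame, matching image conventions, while the mm
frame stays right-handed.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d


def px_to_mm(rows, cols, offset_mm, pixel_size_mm, height):
    """Map pixel-center (row, col) coordinates to plate mm coordinates."""
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    x = offset_mm[0] + (cols + 0.5) * pixel_size_mm
    y = offset_mm[1] + (height - rows - 0.5) * pixel_size_mm
    return x, y


def mm_to_px(x, y, offset_mm, pixel_size_mm, height):
    """Inverse of :func:`px_to_mm`; returns float (row, col) coordinates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cols = (x - offset_mm[0]) / pixel_size_mm - 0.5
    rows = height - (y - offset_mm[1]) / pixel_size_mm - 0.5
    return rows, cols


def polyline_length(points):
    """Total arc length of an (N, 2) polyline."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


def smooth_polyline(points, window=3):
    """Moving-average smoothing of an (N, 2) polyline; endpoints pinned."""
    pts = np.asarray(points, dtype=float)
    if window <= 1 or len(pts) < 3:
        return pts.copy()
    out = uniform_filter1d(pts, size=window, axis=0, mode="nearest")
    # keep the tips in place so smoothing never shortens the worm
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def resample_polyline(points, n_points):
    """Resample a polyline to ``n_points`` points at equal arc-length spacing."""
    pts = np.asarray(points, dtype=float)
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if len(pts) < 2:
        raise ValueError("need at least 2 points to resample")
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate polyline of zero length")
    target = np.linspace(0.0, total, n_points)
    x = np.interp(target, s, pts[:, 0])
    y = np.interp(target, s, pts[:, 1])
    return np.column_stack([x, y])
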