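"""Spatio-temporal curvature maps (kymographs) of worm posture.

Curvature is measured as the wrapped difference of consecutive segment
tangent angles, in degrees per body segment at fixed K, so magnitudes are
invariant to animal size.  Rows of the map are frames, columns the K-2
interior positions along the body (head at column 0).  Frames where midline
extraction failed (the omega pose) are fully masked and rendered white.
A 3x3 mean filter is applied to the unmasked entries; masked neighbors are
excluded and edge entries renormalize over the neighbors that exist, which
makes the filter mean-preserving in the interior and idempotent on constant
maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.ndimage import convolve
from sklearn.base import BaseEstimator, TransformerMixin

from .midline import Midline

DISPLAY_RANGE = (-30.0, 30.0)


@dataclass
class CurvatureMap:
    """Frames x body-positions matrix of signed curvature (degrees/segment)."""

    values: np.ndarray            # (n_frames, K-2), finite where unmasked
    mask: np.ndarray              # (n_frames, K-2) bool, True = invalid/omega
    times: np.ndarray             # (n_frames,) seconds
    body_coords: np.ndarray       # (K-2,) body coordinate in [0, 1]
    display_range: tuple = DISPLAY_RANGE

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def masked_rows(self) -> np.ndarray:
        return self.mask.all(axis=1)


def curvature_profile(midline: Midline) -> np.ndarray:
    """Signed per-segment curvature of one valid midline, in degrees.

    Tangent angles theta_i of the K-1 segments; curvature c_i =
    wrap(theta_{i+1} - theta_i) in (-180, 180], positive for counter-
    clockwise tangent rotation in the mm frame.
    """
    if not midline.valid:
        raise ValueError("cannot compute curvature of an invalid midline")
    d = np.diff(midline.points, axis=0)
    theta = np.arctan2(d[:, 1], d[:, 0])
    dtheta = np.diff(theta)
    dtheta = (dtheta + np.pi) % (2.0 * np.pi) - np.pi
    return np.degrees(dtheta)


def smooth_map(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Masked 3x3 mean filter with edge renormalization."""
    w = (~mask).astype(float)
    kernel = np.ones((3, 3))
    num = convolve(np.where(mask, 0.0, values) * 1.0, kernel, mode="constant")
    den = convolve(w, kernel, mode="constant")
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    out[mask] = np.nan
    return out


def build_map(
    midlines: List[Midline],
    times: Optional[Sequence[float]] = None,
    frame_rate_hz: Optional[float] = None,
    smooth: bool = True,
    extra_mask_rows: Optional[np.ndarray] = None,
) -> CurvatureMap:
    """Assemble the curvature map from per-frame midlines.

    Invalid frames (and any ``extra_mask_rows``, e.g. omega frames detected
    on otherwise-valid midlines) are fully masked before smoothing.
    """
    if not midlines:
        raise ValueError("need at least one frame")
    n = len(midlines)
    K = next((len(m.points) for m in midlines if m.valid), None)
    if K is None:
        raise ValueError("no valid midlines; cannot size the curvature map")
    ncol = K - 2
    values = np.full((n, ncol), np.nan)
    mask = np.ones((n, ncol), dtype=bool)
    for i, m in enumerate(midlines):
        if m.valid:
            values[i] = curvature_profile(m)
            mask[i] = False
    if extra_mask_rows is not None:
        rows = np.asarray(extra_mask_rows, dtype=bool)
        mask[rows] = True
        values[rows] = np.nan
    if times is None:
        fps = frame_rate_hz if frame_rate_hz else 1.0
        times = np.arange(n) / fps
    times = np.asarray(times, dtype=float)
    if smooth:
        values = smooth_map(values, mask)
        values[mask] = np.nan
    body_coords = (np.arange(1, K - 1)) / (K - 1)
    return CurvatureMap(values=values, mask=mask, times=times, body_coords=body_coords)


def render_map(cmap: CurvatureMap, states=None, path=None, dpi: int = 120):
    """Render the kymograph: time on x, body position on y (head at top),
    diverging colors clipped to the display range, masked frames white, and
    black state bars (forward above, backward below the map).

    ``states`` is an optional StateTrack aligned to the map rows.  Returns
    the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from ._labels import BACKWARD, FORWARD

    if states is not None and len(states.labels) != cmap.n_frames:
        raise ValueError("states not aligned to curvature map rows")

    fig, ax = plt.subplots(figsize=(10, 3.2), dpi=dpi)
    data = np.ma.masked_invalid(cmap.values.T)
    palette = plt.get_cmap("RdBu_r").copy()
    palette.set_bad("white")
    vmin, vmax = cmap.display_range
    extent = (
        float(cmap.times[0]),
        float(cmap.times[-1]) if cmap.n_frames > 1 else float(cmap.times[0]) + 1.0,
        1.0,
        0.0,
    )
    im = ax.imshow(
        np.clip(data, vmin, vmax),
        aspect="auto",
        cmap=palette,
        vmin=vmin,
        vmax=vmax,
        extent=extent,
        interpolation="nearest",
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("body position (head → tail)")
    fig.colorbar(im, ax=ax, label="curvature (deg/segment)")

    if states is not None:
        for label, y in ((FORWARD, -0.04), (BACKWARD, 1.04)):
            for state, start_s, end_s in states.intervals:
                if state == label:
                    ax.plot(
                        [start_s, end_s],
                        [y, y],
                        color="black",
                        linewidth=4,
                        solid_capstyle="butt",
                        clip_on=False,
                    )
        ax.set_ylim(1.08, -0.08)

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=dpi)
        plt.close(fig)
    return fig


class CurvatureMapper(BaseEstimator, TransformerMixin):
    """Midlines -> curvature map, as an sklearn-style transformer."""

    def __init__(self, frame_rate_hz: Optional[float] = None, smooth: bool = True):
        self.frame_rate_hz = frame_rate_hz
        self.smooth = smooth

    def fit(self, X, y=None):
        self.is_fitted_ = True
        return self

    def transform(self, X: List[Midline]) -> CurvatureMap:
        return build_map(X, frame_rate_hz=self.frame_rate_hz, smooth=self.smooth)
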