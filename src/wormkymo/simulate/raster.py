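"""Rasterize posture sequences into synthetic video frames.

Each frame draws the worm as a filled tube around the midline: maximum width
body_length/12 at mid-body, tapering smoothly to 40% of that at head and
tail.  Frames are centered on the worm (emulating a tracking stage that keeps
the animal in view) and the mm position of each frame's origin is recorded in
``FrameStack.offsets_mm`` so analysis code can map pixels back to plate
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._geometry import mm_to_px, resample_polyline
from .posture import PostureSequence

WIDTH_FRACTION = 1.0 / 12.0   # max body width as a fraction of body length
TIP_TAPER = 0.4               # width at the tips relative to max width


@dataclass
class FrameStack:
    """A stack of single-worm video frames plus calibration metadata."""

    frames: np.ndarray          # (n, H, W) float32 intensities
    pixel_size_mm: float
    frame_rate_hz: float
    timestamps: np.ndarray      # (n,) seconds, strictly increasing
    offsets_mm: np.ndarray = None  # (n, 2) mm position of each frame origin

    def __post_init__(self):
        if self.offsets_mm is None:
            self.offsets_mm = np.zeros((len(self.frames), 2))
        if len(self.timestamps) != len(self.frames):
            raise ValueError("timestamps and frames length mismatch")
        if len(self.frames) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def width_profile(s, body_length_mm):
    """Tube width (mm) at body coordinate ``s`` in [0, 1]."""
    s = np.asarray(s, dtype=float)
    w_max = body_length_mm * WIDTH_FRACTION
    return w_max * (TIP_TAPER + (1.0 - TIP_TAPER) * np.sqrt(np.sin(np.pi * s).clip(0)))


def tube_area_mm2(body_length_mm, n=10_000):
    """Analytic area of the straight tube model (integral of the width plus
    half-disc end caps); oracle for segmentation-area tests."""
    s = np.linspace(0.0, 1.0, n)
    w = width_profile(s, body_length_mm)
    area = np.trapezoid(w, s * body_length_mm)
    r_tip = width_profile(0.0, body_length_mm) / 2.0
    return float(area + np.pi * r_tip**2)


def rasterize(
    posture: PostureSequence,
    pixel_size_mm: float,
    image_shape=(128, 128),
    noise_sd: float = 0.0,
    seed: int = 0,
    center: bool = True,
) -> FrameStack:
    """Draw each midline of ``posture`` as a filled tube.

    Parameters
    ----------
    pixel_size_mm : mm per pixel; must be positive.
    image_shape : (H, W) of the output frames.
    noise_sd : optional additive Gaussian intensity noise (foreground = 1).
    center : center every frame on the worm centroid (tracking-stage
        emulation) and record the offset; if False a single fixed offset is
        used and the worm must stay inside the frame.
    """
    if pixel_size_mm <= 0:
        raise ValueError("pixel_size_mm must be positive")
    if posture.n_frames == 0 or posture.midlines.size == 0:
        raise ValueError("empty posture sequence")
    H, W = image_shape
    L = posture.config.body_length_mm
    rng = np.random.default_rng(seed)

    # dense resampling keeps the union-of-discs tube smooth (<0.5 px steps)
    n_dense = max(64, int(np.ceil(L / pixel_size_mm / 0.4)))
    s_dense = np.linspace(0.0, 1.0, n_dense)
    radius_px = width_profile(s_dense, L) / 2.0 / pixel_size_mm
    r_max = float(radius_px.max())

    # stamp offsets within the largest radius
    span = int(np.ceil(r_max)) + 1
    dy, dx = np.mgrid[-span:span + 1, -span:span + 1]
    dy, dx = dy.ravel(), dx.ravel()

    centroids = posture.midlines.mean(axis=1)
    if center:
        offsets = centroids - 0.5 * np.array([W, H]) * pixel_size_mm
    else:
        off0 = centroids[0] - 0.5 * np.array([W, H]) * pixel_size_mm
        offsets = np.tile(off0, (posture.n_frames, 1))

    frames = np.zeros((posture.n_frames, H, W), dtype=np.float32)
    for i in range(posture.n_frames):
        dense = resample_polyline(posture.midlines[i], n_dense)
        rows, cols = mm_to_px(dense[:, 0], dense[:, 1], offsets[i], pixel_size_mm, H)
        if (rows.min() < r_max or cols.min() < r_max
                or rows.max() > H - 1 - r_max or cols.max() > W - 1 - r_max):
            raise ValueError(
                f"worm does not fit in the frame at frame {i}; "
                "increase image_shape or decrease pixel_size_mm"
            )
        rc = np.rint(rows).astype(int)
        cc = np.rint(cols).astype(int)
        # pixel (rc+dy, cc+dx) is foreground if its center lies within the
        # local tube radius of the dense midline point
        pr = rc[:, None] + dy[None, :]
        pc = cc[:, None] + dx[None, :]
        dist = np.hypot(pr - rows[:, None], pc - cols[:, None])
        hit = dist <= radius_px[:, None]
        frames[i][pr[hit], pc[hit]] = 1.0

    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape).astype(np.float32)

    return FrameStack(
        frames=frames,
        pixel_size_mm=pixel_size_mm,
        frame_rate_hz=posture.config.frame_rate_hz,
        timestamps=posture.times.copy(),
        offsets_mm=offsets,
    )
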