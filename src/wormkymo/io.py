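"""File-format plumbing: TIFF video stacks with JSON sidecars, CSV midlines,
maps, states, traces, tracks, and JSON summaries."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd
import tifffile

from .curvature import CurvatureMap
from .midline import Midline
from .scoring import LinearRadialGradient, PlateTrack
from .segmentation import StateTrack, TurnStatistics
from .simulate.posture import PostureSequence
from .simulate.raster import FrameStack


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_frame_stack(stack: FrameStack, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    meta = {
        "pixel_size_mm": stack.pixel_size_mm,
        "frame_rate_hz": stack.frame_rate_hz,
        "timestamps_s": stack.timestamps.tolist(),
        "offsets_mm": stack.offsets_mm.tolist(),
    }
    _sidecar(path).write_text(json.dumps(meta))
    return path


def read_frame_stack(path) -> FrameStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(_sidecar(path).read_text())
    return FrameStack(
        frames=frames,
        pixel_size_mm=meta["pixel_size_mm"],
        frame_rate_hz=meta["frame_rate_hz"],
        timestamps=np.asarray(meta["timestamps_s"]),
        offsets_mm=np.asarray(meta["offsets_mm"]),
    )


def write_posture_csv(posture: PostureSequence, midlines_path, states_path):
    n, K, _ = posture.midlines.shape
    frames = np.repeat(np.arange(n), K)
    df = pd.DataFrame(
        {
            "frame": frames,
            "time_s": np.repeat(posture.times, K),
            "point_index": np.tile(np.arange(K), n),
            "x_mm": posture.midlines[:, :, 0].ravel(),
            "y_mm": posture.midlines[:, :, 1].ravel(),
        }
    )
    df.to_csv(midlines_path, index=False)
    pd.DataFrame(
        {"frame": np.arange(n), "time_s": posture.times, "true_state": posture.true_state}
    ).to_csv(states_path, index=False)


def write_midlines_csv(midlines: List[Midline], path):
    rows = []
    for i, m in enumerate(midlines):
        if m.valid:
            for j, (x, y) in enumerate(m.points):
                rows.append((i, True, m.failure_reason, j, x, y))
        else:
            rows.append((i, False, m.failure_reason, -1, np.nan, np.nan))
    pd.DataFrame(
        rows, columns=["frame", "valid", "failure_reason", "point_index", "x_mm", "y_mm"]
    ).to_csv(path, index=False)


def write_curvature_map(cmap: CurvatureMap, csv_path, meta_path):
    pd.DataFrame(cmap.values).to_csv(csv_path, index=False)
    meta = {
        "times_s": cmap.times.tolist(),
        "body_coords": cmap.body_coords.tolist(),
        "display_range": list(cmap.display_range),
        "masked_rows": cmap.masked_rows().tolist(),
    }
    Path(meta_path).write_text(json.dumps(meta))


def write_states(states: StateTrack, states_path, intervals_path):
    pd.DataFrame(
        {
            "frame": np.arange(len(states.labels)),
            "time_s": states.times,
            "label": states.labels,
        }
    ).to_csv(states_path, index=False)
    pd.DataFrame(
        states.intervals, columns=["state", "start_s", "end_s"]
    ).to_csv(intervals_path, index=False)


def write_turn_statistics(stats: TurnStatistics, path):
    Path(path).write_text(
        json.dumps(
            {
                "omega_onsets_s": stats.omega_onsets_s.tolist(),
                "inter_omega_durations_s": stats.inter_omega_durations_s.tolist(),
                "mean_s": stats.mean_s,
                "sem_s": stats.sem_s,
                "analysis_window_s": stats.analysis_window_s,
            },
            indent=2,
        )
    )


def write_track_csv(track: PlateTrack, path):
    track.to_frame().to_csv(path, index=False)


def read_track_csv(path, plate_radius_mm=45.0, gradient=True, peak=None) -> PlateTrack:
    df = pd.read_csv(path)
    return PlateTrack(
        time_s=df["time_s"].to_numpy(),
        x_mm=df["x_mm"].to_numpy(),
        y_mm=df["y_mm"].to_numpy(),
        plate_radius_mm=plate_radius_mm,
        gradient=LinearRadialGradient(plate_radius_mm=plate_radius_mm) if gradient else None,
        peak=peak,
    )


def write_trace_csv(df: pd.DataFrame, path):
    df.to_csv(path, index=False)


def read_trace_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
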