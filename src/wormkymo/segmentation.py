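"""Behavioral-state segmentation: FORWARD / BACKWARD / OMEGA / UNKNOWN.

Omega turns are detected per frame from the midlines themselves: a frame is
an omega candidate when extraction failed with a self-contact-type reason,
or when two midline points separated by more than a quarter of the body arc
length come within one body width of each other.  Candidate runs are merged
across sub-0.3-s gaps and runs shorter than 0.2 s are discarded.

Forward versus backward is decided by the travel direction of the body
wave: for consecutive curvature profiles the body shift maximizing their
correlation is found (searching +/-10 positions); a shift toward the tail
means the wave travels head->tail (forward crawling), toward the head means
backward.  Correlation curves are averaged over a sliding window before the
argmax, low-peak or zero-shift frames are UNKNOWN, and direction blips
shorter than a persistence threshold are absorbed into the surrounding
state.

Inter-omega-turn statistics are onset-to-onset durations within an analysis
window (default the first 1000 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from ._labels import BACKWARD, FORWARD, OMEGA, UNKNOWN
from .curvature import CurvatureMap, build_map
from .midline import Midline
from .simulate.raster import WIDTH_FRACTION

_OMEGA_FAILURES = {"self_contact", "skeleton_branch", "too_short"}


@dataclass
class StateTrack:
    """Per-frame behavioral labels plus the maximal-run intervals."""

    labels: np.ndarray            # (n,) in {FORWARD, BACKWARD, OMEGA, UNKNOWN}
    times: np.ndarray             # (n,) seconds
    frame_rate_hz: float

    @property
    def intervals(self):
        """Maximal runs as (state, start_s, end_s); they partition the
        recording, each end being the start of the next run (the last run
        ends one frame period after its last frame)."""
        out = []
        n = len(self.labels)
        start = 0
        for i in range(1, n + 1):
            if i == n or self.labels[i] != self.labels[start]:
                end_s = (
                    self.times[i] if i < n
                    else self.times[-1] + 1.0 / self.frame_rate_hz
                )
                out.append((str(self.labels[start]), float(self.times[start]), float(end_s)))
                start = i
        return out

    def omega_onsets_s(self) -> np.ndarray:
        return np.array([s for st, s, _ in self.intervals if st == OMEGA])


@dataclass
class TurnStatistics:
    """Onset-to-onset inter-omega-turn durations within an analysis window."""

    omega_onsets_s: np.ndarray
    inter_omega_durations_s: np.ndarray
    mean_s: Optional[float]
    sem_s: Optional[float]
    analysis_window_s: float = 1000.0


# ---------------------------------------------------------------------------
# omega detection


def _self_proximity(points: np.ndarray, body_width_mm: float, min_sep_frac: float) -> bool:
    """True when two points separated by more than ``min_sep_frac`` of the
    body arc length lie within one body width of each other."""
    K = len(points)
    d = squareform(pdist(points))
    idx = np.arange(K)
    sep = np.abs(idx[:, None] - idx[None, :]) / (K - 1)
    cand = sep > min_sep_frac
    return bool(np.any(d[cand] < body_width_mm))


def detect_omega(
    midlines: List[Midline],
    frame_rate_hz: float,
    body_length_mm: Optional[float] = None,
    body_width_mm: Optional[float] = None,
    min_sep_frac: float = 0.25,
    merge_gap_s: float = 0.3,
    min_duration_s: float = 0.2,
) -> np.ndarray:
    """Per-frame omega flags from extraction failures and self-proximity."""
    if body_length_mm is None:
        lengths = [m.length_mm for m in midlines if m.valid]
        if not lengths:
            return np.ones(len(midlines), dtype=bool)
        body_length_mm = float(np.median(lengths))
    if body_width_mm is None:
        body_width_mm = body_length_mm * WIDTH_FRACTION

    cand = np.zeros(len(midlines), dtype=bool)
    for i, m in enumerate(midlines):
        if not m.valid:
            cand[i] = m.failure_reason in _OMEGA_FAILURES
        else:
            cand[i] = _self_proximity(m.points, body_width_mm, min_sep_frac)

    return _merge_and_filter(cand, frame_rate_hz, merge_gap_s, min_duration_s)


def _merge_and_filter(cand, frame_rate_hz, merge_gap_s, min_duration_s):
    cand = cand.copy()
    max_gap = int(round(merge_gap_s * frame_rate_hz))
    min_len = int(round(min_duration_s * frame_rate_hz))
    # merge candidate runs across short gaps
    runs = _runs(cand)
    for k in range(len(runs) - 1):
        (s0, e0, v0), (s1, e1, v1) = runs[k], runs[k + 1]
        if v0 and not v1 and k + 2 <= len(runs) - 1 and (e1 - s1) < max_gap:
            cand[s1:e1] = True
    # drop short runs
    for s, e, v in _runs(cand):
        if v and (e - s) < min_len:
            cand[s:e] = False
    return cand


def _runs(flags):
    """Maximal runs of a boolean/label array as (start, end_exclusive, value)."""
    out = []
    start = 0
    for i in range(1, len(flags) + 1):
        if i == len(flags) or flags[i] != flags[start]:
            out.append((start, i, flags[start]))
            start = i
    return out


# ---------------------------------------------------------------------------
# forward / backward classification


def classify_direction(
    cmap: CurvatureMap,
    window_s: float = 1.0,
    max_shift: int = 10,
    corr_floor: float = 0.5,
    min_persist_s: float = 0.5,
    frame_step: Optional[int] = None,
) -> np.ndarray:
    """Per-frame FORWARD/BACKWARD/UNKNOWN labels from wave travel direction.

    Profiles at t and t + ``frame_step`` frames are compared; by default the
    step spans about a sixth of a second so the undulatory wave travels
    several body positions between the compared profiles, which keeps the
    shift estimate well away from the zero-shift correlation that pixel-
    level extraction noise produces between near-simultaneous frames.

    Omega/masked rows come back UNKNOWN here; the caller overrides them with
    OMEGA when assembling the full state track.
    """
    fps = 1.0 / np.median(np.diff(cmap.times)) if cmap.n_frames > 1 else 1.0
    win = int(round(window_s * fps))
    if win < 2:
        raise ValueError("window_s must span at least 2 frames")
    step = frame_step if frame_step is not None else max(1, int(round(fps / 6.0)))

    V = cmap.values
    n, ncol = V.shape
    row_ok = ~cmap.masked_rows()
    labels = np.full(n, UNKNOWN, dtype="<U8")
    if n <= step:
        return labels

    shifts = np.arange(-max_shift, max_shift + 1)
    # correlation of profile t against profile t+step shifted by delta
    corr = np.full((n - step, len(shifts)), np.nan)
    pair_ok = row_ok[:-step] & row_ok[step:]
    X = np.where(np.isnan(V), 0.0, V)
    for j, delta in enumerate(shifts):
        if delta >= 0:
            a = X[:-step, : ncol - delta]
            b = X[step:, delta:]
        else:
            a = X[:-step, -delta:]
            b = X[step:, : ncol + delta]
        am = a - a.mean(axis=1, keepdims=True)
        bm = b - b.mean(axis=1, keepdims=True)
        denom = np.sqrt((am**2).sum(axis=1) * (bm**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr[:, j] = np.where(denom > 0, (am * bm).sum(axis=1) / denom, np.nan)
    corr[~pair_ok] = np.nan

    # average the correlation curves over the sliding window (valid pairs only)
    w = np.isfinite(corr).astype(float)
    csum = uniform_filter1d(np.nan_to_num(corr), size=win, axis=0, mode="nearest")
    wsum = uniform_filter1d(w, size=win, axis=0, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(wsum > 0, csum / wsum, np.nan)

    for i in range(n - step):
        if not row_ok[i] or not np.any(np.isfinite(avg[i])):
            continue
        j = int(np.nanargmax(avg[i]))
        peak = avg[i, j]
        delta = shifts[j]
        if peak < corr_floor or delta == 0:
            labels[i] = UNKNOWN
        elif delta > 0:
            labels[i] = FORWARD
        else:
            labels[i] = BACKWARD
    for i in range(n - step, n):   # trailing frames inherit the last estimate
        if row_ok[i] and i > 0:
            labels[i] = labels[i - 1]

    return _absorb_blips(labels, fps, min_persist_s)


def _absorb_blips(labels, fps, min_persist_s):
    """Direction changes shorter than the persistence threshold are absorbed
    into the surrounding state (the longer flank wins when flanks differ)."""
    labels = labels.copy()
    min_len = int(round(min_persist_s * fps))
    changed = True
    while changed:
        changed = False
        runs = [r for r in _runs(labels)]
        for k, (s, e, v) in enumerate(runs):
            if v not in (FORWARD, BACKWARD) or (e - s) >= min_len:
                continue
            left = runs[k - 1][2] if k > 0 else None
            right = runs[k + 1][2] if k < len(runs) - 1 else None
            if left in (FORWARD, BACKWARD) and (
                right == left or right not in (FORWARD, BACKWARD)
            ):
                repl = left
            elif right in (FORWARD, BACKWARD):
                repl = right
            else:
                continue
            if repl != v:
                labels[s:e] = repl
                changed = True
                break
    return labels


# ---------------------------------------------------------------------------
# assembly and statistics


def segment_states(
    midlines: List[Midline],
    frame_rate_hz: float,
    omega_kwargs: Optional[dict] = None,
    direction_kwargs: Optional[dict] = None,
):
    """Full segmentation: omega detection, curvature map with omega rows
    masked, direction classification, and the assembled StateTrack.

    Returns ``(states, cmap, omega_flags)``; the OMEGA intervals of the
    state track coincide exactly with the fully masked rows of the map.
    """
    omega = detect_omega(midlines, frame_rate_hz, **(omega_kwargs or {}))
    invalid = np.array([not m.valid for m in midlines])
    cmap = build_map(
        midlines,
        frame_rate_hz=frame_rate_hz,
        extra_mask_rows=omega | invalid,
    )
    labels = classify_direction(cmap, **(direction_kwargs or {}))
    labels = labels.copy()
    labels[omega | invalid] = OMEGA
    states = StateTrack(labels=labels, times=cmap.times, frame_rate_hz=frame_rate_hz)
    return states, cmap, omega


def turn_statistics(states: StateTrack, window_s: float = 1000.0) -> TurnStatistics:
    """Onset-to-onset inter-omega durations within the first ``window_s``.

    With fewer than two onsets the durations are empty and the mean is
    reported as missing (None), never as zero.
    """
    onsets = states.omega_onsets_s()
    onsets = onsets[onsets < window_s]
    if len(onsets) >= 2:
        durations = np.diff(onsets)
        mean = float(durations.mean())
        sem = (
            float(durations.std(ddof=1) / np.sqrt(len(durations)))
            if len(durations) > 1
            else None
        )
    else:
        durations = np.empty(0)
        mean = None
        sem = None
    return TurnStatistics(
        omega_onsets_s=onsets,
        inter_omega_durations_s=durations,
        mean_s=mean,
        sem_s=sem,
        analysis_window_s=window_s,
    )


def group_turn_statistics(stats: List[TurnStatistics]):
    """Mean of per-animal mean inter-omega durations +/- SEM across animals
    (animals without a defined mean are excluded)."""
    means = [s.mean_s for s in stats if s.mean_s is not None]
    if not means:
        return {"mean_s": None, "sem_s": None, "n_animals": 0}
    means = np.asarray(means, dtype=float)
    sem = (
        float(means.std(ddof=1) / np.sqrt(len(means))) if len(means) > 1 else None
    )
    return {"mean_s": float(means.mean()), "sem_s": sem, "n_animals": len(means)}


class StateSegmenter(BaseEstimator):
    """Midlines -> per-frame behavioral states (sklearn-style estimator).

    ``fit`` runs the segmentation and stores ``labels_``, ``states_``,
    ``curvature_map_`` and ``omega_flags_``; ``fit_predict`` returns the
    labels.
    """

    def __init__(
        self,
        frame_rate_hz: float = 30.0,
        window_s: float = 1.0,
        max_shift: int = 10,
        corr_floor: float = 0.5,
        min_persist_s: float = 0.5,
        merge_gap_s: float = 0.3,
        min_omega_s: float = 0.2,
        frame_step=None,
    ):
        self.frame_rate_hz = frame_rate_hz
        self.window_s = window_s
        self.max_shift = max_shift
        self.corr_floor = corr_floor
        self.min_persist_s = min_persist_s
        self.merge_gap_s = merge_gap_s
        self.min_omega_s = min_omega_s
        self.frame_step = frame_step

    def fit(self, X: List[Midline], y=None):
        states, cmap, omega = segment_states(
            X,
            self.frame_rate_hz,
            omega_kwargs={
                "merge_gap_s": self.merge_gap_s,
                "min_duration_s": self.min_omega_s,
            },
            direction_kwargs={
                "window_s": self.window_s,
                "max_shift": self.max_shift,
                "corr_floor": self.corr_floor,
                "min_persist_s": self.min_persist_s,
                "frame_step": self.frame_step,
            },
        )
        self.states_ = states
        self.labels_ = states.labels
        self.curvature_map_ = cmap
        self.omega_flags_ = omega
        return self

    def fit_predict(self, X: List[Midline], y=None):
        return self.fit(X).labels_
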