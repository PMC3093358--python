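"""Midline extraction from single-worm video frames.

Per frame: threshold (Otsu by default), keep the largest connected
component, skeletonize, prune spurs shorter than one body width, and — if
the pruned skeleton is a simple endpoint-to-endpoint path — extend the path
tips to the mask boundary, smooth, and resample to K points at equal arc
length.  Frames where this fails are flagged rather than guessed: a cycle in
the skeleton means the worm touches itself (the omega pose), extra branches
or a drastically shortened skeleton likewise mark the frame invalid.

Head/tail identity is resolved afterwards by frame-to-frame endpoint
matching plus a global polarity vote: during the longest run of valid
frames, the head end is the one leading the net displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import networkx as nx
import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize
from sklearn.base import BaseEstimator, TransformerMixin

from ._geometry import polyline_length, px_to_mm, resample_polyline, smooth_polyline
from .simulate.raster import WIDTH_FRACTION, FrameStack

FAILURE_REASONS = ("none", "self_contact", "skeleton_branch", "too_short", "no_worm")


@dataclass
class Midline:
    """An ordered head-to-tail midline, or a flagged extraction failure."""

    points: np.ndarray                      # (K, 2) mm, empty if invalid
    valid: bool
    failure_reason: str = "none"
    low_confidence: bool = False

    def __post_init__(self):
        if self.failure_reason not in FAILURE_REASONS:
            raise ValueError(f"unknown failure_reason {self.failure_reason!r}")
        if self.valid and self.failure_reason != "none":
            raise ValueError("valid midline cannot carry a failure reason")
        if not self.valid and self.failure_reason == "none":
            raise ValueError("invalid midline needs a failure reason")

    @property
    def length_mm(self) -> float:
        return polyline_length(self.points) if self.valid else np.nan


def segment_worm(frame: np.ndarray, threshold_policy="otsu") -> np.ndarray:
    """Binary worm mask: threshold, then keep the largest component.

    ``threshold_policy`` is ``"otsu"`` or a fixed numeric threshold.  An
    all-background frame yields an empty mask (flagged downstream, not an
    error).
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    if frame.max() <= frame.min():
        return np.zeros(frame.shape, dtype=bool)
    if threshold_policy == "otsu":
        thr = threshold_otsu(frame)
    else:
        thr = float(threshold_policy)
    mask = frame > thr
    if not mask.any():
        return mask
    labels = cc_label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """8-connected pixel graph of a skeleton, without spurious diagonal
    triangles: a diagonal edge is added only when the two orthogonal
    neighbors it would bridge are absent."""
    coords = np.argwhere(skel)
    pix = set(map(tuple, coords))
    G = nx.Graph()
    G.add_nodes_from(pix)
    for r, c in pix:
        for dr, dc in ((0, 1), (1, 0)):
            q = (r + dr, c + dc)
            if q in pix:
                G.add_edge((r, c), q, weight=1.0)
        for dr, dc in ((1, 1), (1, -1)):
            q = (r + dr, c + dc)
            if q in pix and (r + dr, c) not in pix and (r, c + dc) not in pix:
                G.add_edge((r, c), q, weight=float(np.sqrt(2.0)))
    return G


def _prune_spurs(G: nx.Graph, max_len_px: float) -> nx.Graph:
    """Iteratively remove side branches shorter than ``max_len_px``."""
    G = G.copy()
    changed = True
    while changed:
        changed = False
        endpoints = [n for n in G.nodes if G.degree(n) == 1]
        for ep in endpoints:
            if ep not in G:
                continue
            branch = [ep]
            length = 0.0
            node = ep
            prev = None
            while True:
                nbrs = [n for n in G.neighbors(node) if n != prev]
                if G.degree(node) > 2 or not nbrs:
                    break
                nxt = nbrs[0]
                length += G.edges[node, nxt]["weight"]
                if G.degree(nxt) > 2:
                    # side branch hit a junction: removable if short
                    if length < max_len_px and len(branch) < G.number_of_nodes():
                        G.remove_nodes_from(branch)
                        changed = True
                    break
                branch.append(nxt)
                prev, node = node, nxt
                if length >= max_len_px:
                    break
    return G


def extract_midline(
    mask: np.ndarray,
    pixel_size_mm: float,
    n_points: int = 50,
    offset_mm=(0.0, 0.0),
    expected_length_mm: Optional[float] = None,
    smooth_window: int = 3,
    min_length_frac: float = 0.7,
) -> Midline:
    """Recover an equal-arc-length midline from a binary worm mask.

    Failure taxonomy: a skeleton cycle => ``self_contact``; more than two
    endpoints after spur pruning => ``skeleton_branch``; a path shorter than
    ``min_length_frac`` of ``expected_length_mm`` => ``too_short``; an empty
    mask => ``no_worm``.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    mask = np.asarray(mask, dtype=bool)
    H = mask.shape[0]
    if not mask.any():
        return Midline(np.empty((0, 2)), valid=False, failure_reason="no_worm")

    skel = skeletonize(mask)
    if not skel.any():
        return Midline(np.empty((0, 2)), valid=False, failure_reason="no_worm")
    G = _skeleton_graph(skel)

    # one-body-width spur pruning; width estimated from the mask itself
    skel_len_px = max(float(G.size(weight="weight")), 1.0)
    width_px = mask.sum() / skel_len_px
    G = _prune_spurs(G, max_len_px=max(3.0, width_px))

    if G.number_of_nodes() == 0:
        return Midline(np.empty((0, 2)), valid=False, failure_reason="too_short")
    if G.number_of_edges() >= G.number_of_nodes():      # connected + cycle
        return Midline(np.empty((0, 2)), valid=False, failure_reason="self_contact")
    endpoints = [n for n in G.nodes if G.degree(n) == 1]
    if len(endpoints) != 2:
        return Midline(np.empty((0, 2)), valid=False, failure_reason="skeleton_branch")

    path = nx.shortest_path(G, endpoints[0], endpoints[1], weight="weight")
    path_px = np.asarray(path, dtype=float)         # (N, 2) as (row, col)
    path_px = _extend_to_boundary(path_px, mask)
    # the mask boundary lies about one tip half-width beyond the midline end;
    # pull each end back by that margin (~= 0.2 of the mean body width)
    path_px = _trim_ends(path_px, 0.2 * width_px)

    x, y = px_to_mm(path_px[:, 0], path_px[:, 1], offset_mm, pixel_size_mm, H)
    pts = np.column_stack([x, y])
    if expected_length_mm is not None:
        if polyline_length(pts) < min_length_frac * expected_length_mm:
            return Midline(np.empty((0, 2)), valid=False, failure_reason="too_short")
    pts = smooth_polyline(pts, window=smooth_window)
    pts = resample_polyline(pts, n_points)
    return Midline(pts, valid=True)


def _extend_to_boundary(path_px: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extend both path ends along the local tangent to the mask boundary.

    Skeletonization stops roughly one tip radius short of the worm's ends;
    this restores the full body length.
    """
    H, W = mask.shape
    out = [path_px]
    for end, inner in ((0, min(4, len(path_px) - 1)), (-1, max(-5, -len(path_px)))):
        p = path_px[end]
        d = p - path_px[inner]
        norm = np.hypot(*d)
        if norm == 0:
            continue
        d = d / norm
        tip = p.copy()
        step = 0.5
        for k in range(1, 80):
            q = p + d * step * k
            r, c = int(round(q[0])), int(round(q[1]))
            if r < 0 or r >= H or c < 0 or c >= W or not mask[r, c]:
                break
            tip = q
        if end == 0:
            out.insert(0, tip[None, :])
        else:
            out.append(tip[None, :])
    return np.vstack(out)


def _trim_ends(path_px: np.ndarray, trim_len_px: float) -> np.ndarray:
    """Shorten both ends of a polyline by ``trim_len_px`` of arc length."""
    if trim_len_px <= 0 or len(path_px) < 3:
        return path_px
    seg = np.hypot(*np.diff(path_px, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 2.5 * trim_len_px:
        return path_px
    lo, hi = trim_len_px, total - trim_len_px
    keep = (s > lo) & (s < hi)
    head = np.array(
        [np.interp(lo, s, path_px[:, 0]), np.interp(lo, s, path_px[:, 1])]
    )
    tail = np.array(
        [np.interp(hi, s, path_px[:, 0]), np.interp(hi, s, path_px[:, 1])]
    )
    return np.vstack([head[None, :], path_px[keep], tail[None, :]])


def orient_and_track(midlines: List[Midline]) -> List[Midline]:
    """Return midlines consistently ordered head -> tail.

    Within each contiguous run of valid frames the orientation is chained by
    nearest-endpoint matching to the previous valid frame.  Polarity is then
    fixed per run by the displacement rule: the head end is the one leading
    the run's net centroid displacement.  Across invalid (omega) gaps the
    animal reorients by more than a right angle and the head visits the tail
    region, so endpoint identity is deliberately NOT carried over a gap —
    each run re-derives its own polarity, falling back to endpoint matching
    against the previous run only when the run shows no net displacement.
    Runs resolved without displacement evidence are flagged low-confidence.
    """
    valid_idx = [i for i, m in enumerate(midlines) if m.valid]
    if not valid_idx:
        raise ValueError("no valid midlines to orient")

    oriented = [
        Midline(m.points.copy(), m.valid, m.failure_reason, m.low_confidence)
        for m in midlines
    ]

    # contiguous runs of valid frames
    runs = []
    start = prev_i = valid_idx[0]
    for i in valid_idx[1:]:
        if i != prev_i + 1:
            runs.append((start, prev_i))
            start = i
        prev_i = i
    runs.append((start, prev_i))

    prev_last = None
    for s, e in runs:
        frames = [oriented[i] for i in range(s, e + 1)]
        # chain orientation within the run
        for prev, m in zip(frames, frames[1:]):
            keep = (
                np.hypot(*(m.points[0] - prev.points[0]))
                + np.hypot(*(m.points[-1] - prev.points[-1]))
            )
            flip = (
                np.hypot(*(m.points[-1] - prev.points[0]))
                + np.hypot(*(m.points[0] - prev.points[-1]))
            )
            if flip < keep:
                m.points = m.points[::-1].copy()
        # per-run polarity: head leads net displacement
        centroids = np.array([m.points.mean(axis=0) for m in frames])
        disp = centroids[-1] - centroids[0]
        norm = np.hypot(*disp)
        if norm > 1e-9:
            d_hat = disp / norm
            head_lead = np.mean(
                [(m.points[0] - c) @ d_hat for m, c in zip(frames, centroids)]
            )
            if head_lead < 0:
                for m in frames:
                    m.points = m.points[::-1].copy()
        else:
            # no displacement evidence: match endpoints to the previous run
            if prev_last is not None:
                m0 = frames[0]
                keep = np.hypot(*(m0.points[0] - prev_last.points[0]))
                flip = np.hypot(*(m0.points[0] - prev_last.points[-1]))
                if flip < keep:
                    for m in frames:
                        m.points = m.points[::-1].copy()
            for m in frames:
                m.low_confidence = True
        prev_last = frames[-1]
    return oriented


class MidlineExtractor(BaseEstimator, TransformerMixin):
    """Frames -> oriented midlines, as an sklearn-style transformer.

    ``fit`` estimates the animal's body length (``body_length_mm_``) and
    width (``body_width_mm_``) from a sample of frames; ``transform`` runs
    segmentation, midline extraction with a running-median length check, and
    head/tail orientation over the whole stack.
    """

    def __init__(
        self,
        n_points: int = 50,
        threshold_policy="otsu",
        smooth_window: int = 3,
        min_length_frac: float = 0.7,
        fit_sample_frames: int = 50,
    ):
        self.n_points = n_points
        self.threshold_policy = threshold_policy
        self.smooth_window = smooth_window
        self.min_length_frac = min_length_frac
        self.fit_sample_frames = fit_sample_frames

    def fit(self, X: FrameStack, y=None):
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        lengths = []
        widths = []
        step = max(1, X.n_frames // self.fit_sample_frames)
        for i in range(0, X.n_frames, step):
            mask = segment_worm(X.frames[i], self.threshold_policy)
            m = extract_midline(
                mask,
                X.pixel_size_mm,
                n_points=self.n_points,
                offset_mm=X.offsets_mm[i],
                smooth_window=self.smooth_window,
            )
            if m.valid:
                lengths.append(m.length_mm)
                widths.append(
                    mask.sum() * X.pixel_size_mm**2 / max(m.length_mm, 1e-9)
                )
        if not lengths:
            raise ValueError("could not extract any valid midline during fit")
        self.body_length_mm_ = float(np.median(lengths))
        self.body_width_mm_ = float(np.median(widths))
        return self

    def transform(self, X: FrameStack) -> List[Midline]:
        if not hasattr(self, "body_length_mm_"):
            raise ValueError("MidlineExtractor must be fitted before transform")
        midlines = []
        recent = [self.body_length_mm_]
        for i in range(X.n_frames):
            mask = segment_worm(X.frames[i], self.threshold_policy)
            expected = float(np.median(recent))
            m = extract_midline(
                mask,
                X.pixel_size_mm,
                n_points=self.n_points,
                offset_mm=X.offsets_mm[i],
                expected_length_mm=expected,
                smooth_window=self.smooth_window,
                min_length_frac=self.min_length_frac,
            )
            if m.valid:
                recent.append(m.length_mm)
                if len(recent) > 101:
                    recent.pop(0)
            midlines.append(m)
        return orient_and_track(midlines)
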