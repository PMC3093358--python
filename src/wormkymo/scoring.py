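"""Categorical scoring of single-animal plate-assay tracks.

Three assay types are covered:

* radial-gradient thermotaxis — the plate center sits near 17 degC and the
  periphery near 25 degC; each one-hour track is classified as '17', '20',
  '25', or '17/25' according to which temperature zones the animal occupied;
* odorant chemotaxis — the population chemotaxis index
  CI = (n_at_odorant - n_at_control) / n_total;
* NaCl chemotaxis — single animals classified normal / partial / defective
  by how often and how long they visit the concentration peak.

The original classification of tracks was done by eye; here "moved to" a
zone is operationalized as a configurable occupancy threshold (default 10%
of the assay), and the occupancies are always reported so a user can
re-threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

TTX_CATEGORIES = ("17", "20", "25", "17/25")
NACL_CATEGORIES = ("normal", "partial", "defective")

#: default zone boundaries in degC for 20 degC-grown animals on a 17->25 plate
DEFAULT_ZONES = {"17": (-np.inf, 18.5), "20": (19.0, 21.0), "25": (23.5, np.inf)}


@dataclass
class LinearRadialGradient:
    """Monotone radius -> temperature map, linear by default (17 + 8 r/R)."""

    t_center_c: float = 17.0
    t_edge_c: float = 25.0
    plate_radius_mm: float = 45.0
    # optional lookup table (radius_mm, temperature_c) overriding linearity
    table: Optional[np.ndarray] = None

    def temperature_at(self, radius_mm):
        r = np.asarray(radius_mm, dtype=float)
        if self.table is not None:
            tab = np.asarray(self.table, dtype=float)
            return np.interp(r, tab[:, 0], tab[:, 1])
        return self.t_center_c + (self.t_edge_c - self.t_center_c) * r / self.plate_radius_mm

    def radius_at(self, temperature_c):
        """Inverse map (for zone geometry); linear gradients only."""
        if self.table is not None:
            tab = np.asarray(self.table, dtype=float)
            return np.interp(temperature_c, tab[:, 1], tab[:, 0])
        frac = (temperature_c - self.t_center_c) / (self.t_edge_c - self.t_center_c)
        return frac * self.plate_radius_mm


@dataclass
class PlateTrack:
    """Timed 2-D positions of one animal, plate center at the origin."""

    time_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    plate_radius_mm: float = 45.0
    gradient: Optional[LinearRadialGradient] = None
    peak: Optional[tuple] = None      # (x_mm, y_mm, region_radius_mm)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        if len(self.time_s) > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("track times must be strictly increasing")

    @property
    def radius_mm(self) -> np.ndarray:
        return np.hypot(self.x_mm, self.y_mm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time_s, "x_mm": self.x_mm, "y_mm": self.y_mm}
        )


@dataclass
class BehaviorScore:
    ttx_category: Optional[str] = None
    nacl_category: Optional[str] = None
    occupancies: dict = field(default_factory=dict)
    low_confidence: bool = False
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# thermotaxis


def zone_occupancies(track: PlateTrack, zones=None) -> dict:
    """Fraction of samples spent in each temperature zone."""
    if track.gradient is None:
        raise ValueError("track has no temperature gradient defined")
    zones = DEFAULT_ZONES if zones is None else zones
    temp = track.gradient.temperature_at(track.radius_mm)
    return {
        name: float(np.mean((temp >= lo) & (temp <= hi)))
        for name, (lo, hi) in zones.items()
    }


def classify_thermotaxis(track: PlateTrack, zones=None, visit_frac: float = 0.10):
    """Assign one of the four thermotaxis categories to a track.

    A zone counts as visited when its occupancy is at least ``visit_frac``.
    Visiting both the cold (center) and warm (periphery) zones yields
    '17/25'; otherwise the visited zone with the largest occupancy wins.
    Tracks visiting no zone are labeled by their highest occupancy and
    flagged low-confidence.
    """
    occ = zone_occupancies(track, zones)
    visited = {z for z, f in occ.items() if f >= visit_frac}
    low_confidence = False
    if {"17", "25"} <= visited:
        category = "17/25"
    elif visited:
        category = max(visited, key=lambda z: occ[z])
    else:
        category = max(occ, key=occ.get)
        low_confidence = True
    return BehaviorScore(
        ttx_category=category, occupancies=occ, low_confidence=low_confidence
    )


class ThermotaxisClassifier(BaseEstimator):
    """Rule-based four-category thermotaxis classifier (sklearn-style).

    ``fit`` validates the configuration; ``predict`` maps an iterable of
    :class:`PlateTrack` to category labels.  Occupancies for the last call
    are kept in ``scores_``.
    """

    def __init__(self, zones=None, visit_frac: float = 0.10):
        self.zones = zones
        self.visit_frac = visit_frac

    def fit(self, X=None, y=None):
        if not 0.0 < self.visit_frac <= 1.0:
            raise ValueError("visit_frac must be in (0, 1]")
        self.zones_ = DEFAULT_ZONES if self.zones is None else dict(self.zones)
        return self

    def predict(self, X: Sequence[PlateTrack]):
        if not hasattr(self, "zones_"):
            self.fit()
        self.scores_ = [
            classify_thermotaxis(t, self.zones_, self.visit_frac) for t in X
        ]
        return np.array([s.ttx_category for s in self.scores_])


# ---------------------------------------------------------------------------
# chemotaxis index


def chemotaxis_index(n_at_odorant: int, n_at_control: int, n_total: int) -> float:
    """CI = (animals at odorant - animals at control) / total, in [-1, 1]."""
    if n_at_odorant < 0 or n_at_control < 0:
        raise ValueError("counts must be non-negative")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_at_odorant + n_at_control > n_total:
        raise ValueError("scored animals exceed total")
    return (n_at_odorant - n_at_control) / n_total


# ---------------------------------------------------------------------------
# NaCl classification


def classify_nacl(
    track: PlateTrack,
    peak=None,
    min_excursion_s: float = 30.0,
    long_dwell_frac: float = 0.5,
):
    """Classify a NaCl-assay track as normal / partial / defective.

    Distinct entries into the peak region must be separated by at least
    ``min_excursion_s`` spent outside.  'normal' = repeated migration to the
    peak (>= 2 entries) or remaining there (dwell >= ``long_dwell_frac`` of
    the assay); 'partial' = exactly one entry with a short stay;
    'defective' = the peak is never reached.
    """
    peak = peak if peak is not None else track.peak
    if peak is None:
        raise ValueError("no concentration peak defined for this track")
    px, py, pr = peak
    if np.hypot(px, py) > track.plate_radius_mm:
        raise ValueError("peak lies outside the plate")

    inside = np.hypot(track.x_mm - px, track.y_mm - py) <= pr
    t = track.time_s
    dwell_frac = float(np.mean(inside))

    entries = 0
    exit_time = None
    was_inside = bool(inside[0]) if len(inside) else False
    if was_inside:
        entries = 1
    for i in range(1, len(t)):
        if inside[i] and not was_inside:
            # a re-entry only counts after a sufficiently long excursion
            if entries == 0 or (t[i] - exit_time) >= min_excursion_s:
                entries += 1
        elif was_inside and not inside[i]:
            exit_time = t[i]
        was_inside = bool(inside[i])

    if entries >= 2 or dwell_frac >= long_dwell_frac:
        category = "normal"
    elif entries == 1:
        category = "partial"
    else:
        category = "defective"
    return BehaviorScore(
        nacl_category=category,
        details={"entries": entries, "dwell_frac": dwell_frac},
    )


class NaClClassifier(BaseEstimator):
    """Rule-based NaCl normal/partial/defective classifier (sklearn-style)."""

    def __init__(self, peak=None, min_excursion_s: float = 30.0,
                 long_dwell_frac: float = 0.5):
        self.peak = peak
        self.min_excursion_s = min_excursion_s
        self.long_dwell_frac = long_dwell_frac

    def fit(self, X=None, y=None):
        if self.min_excursion_s < 0:
            raise ValueError("min_excursion_s must be >= 0")
        if not 0.0 < self.long_dwell_frac <= 1.0:
            raise ValueError("long_dwell_frac must be in (0, 1]")
        self.is_fitted_ = True
        return self

    def predict(self, X: Sequence[PlateTrack]):
        if not hasattr(self, "is_fitted_"):
            self.fit()
        self.scores_ = [
            classify_nacl(t, self.peak, self.min_excursion_s, self.long_dwell_frac)
            for t in X
        ]
        return np.array([s.nacl_category for s in self.scores_])


# ---------------------------------------------------------------------------
# fraction summaries


def fraction_summary(categories_per_assay, categories=None) -> pd.DataFrame:
    """Per-category fraction mean +/- SEM across independent assays.

    ``categories_per_assay`` is a list of per-assay label lists (one label
    per animal).  Returns a DataFrame indexed by category with columns
    ``mean`` and ``sem`` (SEM is NaN for a single assay).
    """
    if not categories_per_assay or any(len(a) == 0 for a in categories_per_assay):
        raise ValueError("every assay must contain at least one animal")
    if categories is None:
        categories = sorted({c for assay in categories_per_assay for c in assay})
    fracs = np.array(
        [
            [np.mean(np.asarray(assay) == c) for c in categories]
            for assay in categories_per_assay
        ]
    )
    mean = fracs.mean(axis=0)
    if len(fracs) > 1:
        sem = fracs.std(axis=0, ddof=1) / np.sqrt(len(fracs))
    else:
        sem = np.full(len(categories), np.nan)
    return pd.DataFrame({"mean": mean, "sem": sem}, index=list(categories))
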