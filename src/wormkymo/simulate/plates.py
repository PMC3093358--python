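"""Biased-random-walk plate tracks for behavioral-scoring tests.

Tracks follow a run-and-tumble scheme: persistent heading, Poisson-timed
reorientations, small heading diffusion, and an optional drift toward a
target point.  Archetype parameter sets script the track styles the scoring
rules must distinguish:

``stay-center``, ``stay-periphery``, ``stay-ring``
    drift toward a target radius (thermotaxis categories '17', '25', '20');
``wander-both``
    target radius alternates between center and periphery ('17/25');
``approach-peak-k-times``
    NaCl assay: the animal migrates to the concentration peak ``k`` times
    with long excursions in between (k=0 scripts a defective track that
    never approaches the peak).
"""

from __future__ import annotations

import numpy as np

from ..scoring import LinearRadialGradient, PlateTrack

KINDS = ("thermotaxis", "nacl", "chemotaxis")

_ARCHETYPES = (
    "stay-center",
    "stay-periphery",
    "stay-ring",
    "wander-both",
    "approach-peak-k-times",
)


def _unit(v):
    n = np.hypot(v[0], v[1])
    return v / n if n > 0 else np.array([1.0, 0.0])


def simulate_plate_track(
    kind: str,
    behavior_params: dict | None = None,
    seed: int = 0,
) -> PlateTrack:
    """Generate one synthetic plate track of the requested assay ``kind``.

    ``behavior_params`` keys (all optional): ``archetype``, ``duration_s``,
    ``dt_s``, ``speed_mm_s``, ``plate_radius_mm``, ``tumble_rate_per_s``,
    ``drift_weight``, ``heading_noise_rad``, ``k`` (peak approaches),
    ``peak`` ((x, y, region_radius_mm)), ``start_radius_frac``.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown assay kind {kind!r}; expected one of {KINDS}")
    p = dict(behavior_params or {})
    archetype = p.get("archetype", "stay-center")
    if archetype not in _ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")

    R = float(p.get("plate_radius_mm", 45.0))
    if R <= 0:
        raise ValueError("plate radius must be positive")
    duration = float(p.get("duration_s", 1200.0))
    dt = float(p.get("dt_s", 1.0))
    # wandering animals cover both ends of the plate; give them the brisker
    # crawling speed of a roaming worm by default
    default_speed = 0.35 if archetype == "wander-both" else 0.2
    speed = float(p.get("speed_mm_s", default_speed))
    tumble_rate = float(p.get("tumble_rate_per_s", 0.05))
    drift_w = float(p.get("drift_weight", 0.4))
    noise = float(p.get("heading_noise_rad", 0.15))
    k_approaches = int(p.get("k", 3))
    peak = p.get("peak", (0.5 * R, 0.0, 5.0))
    start_frac = float(p.get("start_radius_frac", 0.25))

    rng = np.random.default_rng(seed)
    n = max(2, int(round(duration / dt)) + 1)
    t = np.arange(n) * dt

    # target schedule -------------------------------------------------------
    ring_r = {"stay-center": 0.02 * R, "stay-periphery": 0.93 * R,
              "stay-ring": 0.375 * R}
    switch_s = float(p.get("switch_s", duration / 4.0))

    pos = start_frac * R * np.array(
        [np.cos(a := rng.uniform(0, 2 * np.pi)), np.sin(a)]
    )
    heading = rng.uniform(0, 2 * np.pi)
    xs = np.empty(n)
    ys = np.empty(n)
    xs[0], ys[0] = pos

    # state for approach-peak-k-times phase scripting
    peak_xy = np.array(peak[:2])
    phase = "approach" if k_approaches > 0 else "avoid"
    approaches_done = 0
    dwell_left = float(p.get("dwell_s", 60.0))
    away_point = None

    for i in range(1, n):
        # pick the current drift target
        if archetype in ring_r:
            target = _unit(pos) * ring_r[archetype] if np.any(pos) else np.zeros(2)
        elif archetype == "wander-both":
            inner = (int(t[i] / switch_s) % 2) == 0
            rr = 0.02 * R if inner else 0.93 * R
            target = _unit(pos) * rr if np.any(pos) else np.zeros(2)
        else:  # approach-peak-k-times
            if phase == "approach":
                target = peak_xy
                if np.hypot(*(pos - peak_xy)) < 0.5 * peak[2]:
                    phase = "dwell"
                    dwell_left = float(p.get("dwell_s", 60.0))
            if phase == "dwell":
                target = peak_xy
                dwell_left -= dt
                if dwell_left <= 0:
                    approaches_done += 1
                    if approaches_done < k_approaches:
                        phase = "retreat"
                        away_point = -_unit(peak_xy) * 0.6 * R
                    else:
                        phase = "retreat-final"
                        away_point = -_unit(peak_xy) * 0.6 * R
            if phase in ("retreat", "retreat-final"):
                target = away_point
                if np.hypot(*(pos - away_point)) < 0.1 * R:
                    phase = "approach" if phase == "retreat" else "wander"
            if phase == "wander":
                target = -_unit(peak_xy) * 0.5 * R
            if phase == "avoid":
                # never approach the peak: hold to the opposite half-plate
                target = -_unit(peak_xy) * 0.5 * R

        # run-and-tumble heading update
        if rng.random() < 1.0 - np.exp(-tumble_rate * dt):
            heading = rng.uniform(0, 2 * np.pi)
        heading += rng.normal(0.0, noise * np.sqrt(dt))
        direction = (1.0 - drift_w) * np.array([np.cos(heading), np.sin(heading)])
        to_target = target - pos
        if np.hypot(*to_target) > 1e-9:
            direction = direction + drift_w * _unit(to_target)
        direction = _unit(direction)
        heading = np.arctan2(direction[1], direction[0])

        new = pos + speed * dt * direction
        if archetype == "approach-peak-k-times" and phase in ("avoid",):
            # hard exclusion: a defective animal never reaches the peak region
            d = np.hypot(*(new - peak_xy))
            if d < 2.0 * peak[2]:
                new = peak_xy + _unit(new - peak_xy) * 2.0 * peak[2]
        r = np.hypot(*new)
        if r > R:  # reflect at the plate wall
            new = new * (2 * R - r) / r
            heading = rng.uniform(0, 2 * np.pi)
        pos = new
        xs[i], ys[i] = pos

    gradient = (
        LinearRadialGradient(plate_radius_mm=R) if kind == "thermotaxis" else None
    )
    return PlateTrack(
        time_s=t,
        x_mm=xs,
        y_mm=ys,
        plate_radius_mm=R,
        gradient=gradient,
        peak=tuple(peak) if kind in ("nacl", "chemotaxis") else None,
        meta={"kind": kind, "archetype": archetype, "seed": seed,
              "k": k_approaches},
    )
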