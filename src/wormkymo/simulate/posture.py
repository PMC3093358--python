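"""Synthetic worm posture sequences with ground-truth behavioral labels.

The generator produces an inextensible worm whose body tangent angle follows a
traveling sine wave

    theta(s, t) = psi(t) + A * sin(2*pi*s/lambda - phase(t))

with body coordinate ``s`` in body lengths (0 = head, 1 = tail).  During
forward runs the phase advances so the wave travels head->tail; during
reversals the phase direction flips (wave travels tail->head).  Omega turns
are scripted: the sine wave is blended into a stereotyped high-curvature
anterior curl that brings the head within one body width of the posterior
body, while the heading ``psi`` rotates by 120-180 degrees, after which
forward crawling resumes in the new direction.

Omega and reversal onsets are independent Poisson processes.  Overlapping
omega intervals merge into one ground-truth OMEGA run; a reversal is truncated
by an omega onset and a reversal onset inside an omega is discarded, so the
three states are mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .._labels import BACKWARD, FORWARD, OMEGA

# Omega-pose geometry: total anterior tangent rotation (rad) and the fraction
# of the body over which the curl is distributed.  5.8 rad over the anterior
# 70% closes the curl far enough that the head approaches the posterior body
# to well under one body width (body width = body_length / 12).
_OMEGA_TOTAL_TURN_RAD = 6.0
_OMEGA_CURL_EXTENT = 0.7
# Fraction of the omega duration spent ramping into / out of the curl.
_OMEGA_RAMP_FRAC = 0.09


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic locomotion generator.

    Defaults are typical for a freely crawling adult C. elegans: 1 mm body,
    0.6 rad bend amplitude, 0.9 body-length undulation wavelength, 0.5 Hz
    wave frequency and 0.15 mm/s forward speed, filmed at 30 frames/s.
    """

    duration_s: float = 60.0
    frame_rate_hz: float = 30.0
    body_length_mm: float = 1.0
    n_midline_points: int = 50
    wave_amplitude_rad: float = 0.6
    wave_wavelength_bodylengths: float = 0.9
    wave_frequency_hz: float = 0.5
    forward_speed_mm_s: float = 0.15
    omega_rate_per_s: float = 0.0
    omega_duration_s: float = 2.0
    reversal_rate_per_s: float = 0.0
    reversal_duration_s: float = 3.0
    rng_seed: int = 0

    def validate(self) -> "SimulationConfig":
        numeric = {
            "duration_s": self.duration_s,
            "frame_rate_hz": self.frame_rate_hz,
            "body_length_mm": self.body_length_mm,
            "wave_amplitude_rad": self.wave_amplitude_rad,
            "wave_wavelength_bodylengths": self.wave_wavelength_bodylengths,
            "wave_frequency_hz": self.wave_frequency_hz,
            "forward_speed_mm_s": self.forward_speed_mm_s,
            "omega_rate_per_s": self.omega_rate_per_s,
            "omega_duration_s": self.omega_duration_s,
            "reversal_rate_per_s": self.reversal_rate_per_s,
            "reversal_duration_s": self.reversal_duration_s,
        }
        for name, value in numeric.items():
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
        for name in ("omega_rate_per_s", "reversal_rate_per_s",
                     "wave_amplitude_rad", "forward_speed_mm_s"):
            if numeric[name] < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("duration_s", "frame_rate_hz", "body_length_mm",
                     "wave_wavelength_bodylengths", "wave_frequency_hz",
                     "omega_duration_s", "reversal_duration_s"):
            if numeric[name] <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_midline_points < 10:
            raise ValueError("n_midline_points must be >= 10")
        return self


@dataclass
class PostureSequence:
    """Simulated midlines plus per-frame ground-truth behavioral labels."""

    times: np.ndarray                 # (n_frames,) seconds
    midlines: np.ndarray              # (n_frames, K, 2) mm, head -> tail
    true_state: np.ndarray            # (n_frames,) labels in {FORWARD, BACKWARD, OMEGA}
    config: SimulationConfig
    omega_intervals_s: list = field(default_factory=list)   # [(start, end)]
    reversal_intervals_s: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def omega_onsets_s(self) -> np.ndarray:
        return np.array([s for s, _ in self.omega_intervals_s])

    def state_time_fraction(self, label: str) -> float:
        return float(np.mean(self.true_state == label))


def _poisson_onsets(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    """Event onsets of a homogeneous Poisson process on [0, duration)."""
    if rate <= 0:
        return np.empty(0)
    onsets = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        onsets.append(t)
    return np.asarray(onsets)


def _merge_intervals(intervals):
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for start, end in intervals[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(iv) for iv in merged]


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def simulate_posture_sequence(config: SimulationConfig) -> PostureSequence:
    """Generate a labeled posture sequence from ``config``.

    Identical config (including ``rng_seed``) yields bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    fps = config.frame_rate_hz
    n = max(1, int(round(config.duration_s * fps)))
    times = np.arange(n) / fps
    K = config.n_midline_points
    L = config.body_length_mm

    # --- event schedule -----------------------------------------------------
    omega_onsets = _poisson_onsets(rng, config.omega_rate_per_s, config.duration_s)
    rev_onsets = _poisson_onsets(rng, config.reversal_rate_per_s, config.duration_s)
    omega_raw = [(o, o + config.omega_duration_s) for o in omega_onsets]
    omega_iv = _merge_intervals(omega_raw)

    def in_omega(t):
        return any(s <= t < e for s, e in omega_iv)

    rev_iv = []
    for o in rev_onsets:
        if in_omega(o):
            continue  # exclusive states: drop a reversal starting mid-omega
        end = o + config.reversal_duration_s
        for s, _ in omega_iv:
            if o < s < end:
                end = s  # omega onset truncates the reversal
                break
        if end > o:
            rev_iv.append((o, end))
    rev_iv = _merge_intervals(rev_iv)

    # one reorientation angle per merged omega event, 120-180 deg, random side
    turn_angles = np.deg2rad(rng.uniform(120.0, 180.0, size=len(omega_iv)))
    turn_angles *= rng.choice([-1.0, 1.0], size=len(omega_iv))

    # --- per-frame state ----------------------------------------------------
    state = np.full(n, FORWARD, dtype="<U8")
    for s, e in rev_iv:
        state[(times >= s) & (times < e)] = BACKWARD
    for s, e in omega_iv:
        state[(times >= s) & (times < e)] = OMEGA

    # --- wave phase, heading, omega blend ----------------------------------
    # wave direction: head->tail (+1) except during reversals
    sigma = np.where(state == BACKWARD, -1.0, 1.0)
    # integrated phase starting at 0 for frame 0 (cumsum excludes the
    # current frame so theta(s, t=0) matches the analytic field exactly)
    phase = (
        2.0 * np.pi * config.wave_frequency_hz * (np.cumsum(sigma) - sigma) / fps
    )

    psi = np.zeros(n)
    blend = np.zeros(n)
    curl_sign = np.zeros(n)
    for (s, e), dpsi in zip(omega_iv, turn_angles):
        u = (times - s) / (e - s)
        psi += dpsi * _smoothstep(u)
        ramp = np.clip(np.minimum(u, 1.0 - u) / _OMEGA_RAMP_FRAC, 0.0, 1.0)
        active = (u >= 0.0) & (u < 1.0)
        take = active & (ramp > blend)
        blend[take] = ramp[take]
        curl_sign[take] = np.sign(dpsi)

    # --- tangent-angle field and midline integration ------------------------
    s_mid = (np.arange(K - 1) + 0.5) / (K - 1)      # body coord of segment midpoints
    wave = config.wave_amplitude_rad * np.sin(
        2.0 * np.pi * s_mid[None, :] / config.wave_wavelength_bodylengths
        - phase[:, None]
    )
    curl = _OMEGA_TOTAL_TURN_RAD * (
        1.0 - np.clip(s_mid / _OMEGA_CURL_EXTENT, 0.0, 1.0)
    )
    theta = (
        psi[:, None]
        + (1.0 - blend[:, None]) * wave
        + (blend * curl_sign)[:, None] * curl[None, :]
    )

    ds = L / (K - 1)
    seg = np.stack([np.cos(theta), np.sin(theta)], axis=-1) * ds   # (n, K-1, 2)
    pts = np.zeros((n, K, 2))
    pts[:, 1:] = np.cumsum(seg, axis=1)

    # translate so the centroid follows the locomotion track; forward motion
    # is toward the head, i.e. against the head->tail tangent direction
    move_sign = np.where(state == BACKWARD, -1.0, 1.0)
    vel = (
        -config.forward_speed_mm_s
        * move_sign[:, None]
        * np.stack([np.cos(psi), np.sin(psi)], axis=-1)
    )
    track = np.vstack([[0.0, 0.0], np.cumsum(vel[:-1] / fps, axis=0)])
    centroid = pts.mean(axis=1)
    pts += (track - centroid)[:, None, :]

    return PostureSequence(
        times=times,
        midlines=pts,
        true_state=state,
        config=config,
        omega_intervals_s=omega_iv,
        reversal_intervals_s=rev_iv,
    )
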