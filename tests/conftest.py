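"""Shared fixtures: one mid-sized rasterized simulation reused across the
midline / curvature / segmentation tests to keep the suite fast."""

import numpy as np
import pytest

from wormkymo import (
    MidlineExtractor,
    SimulationConfig,
    rasterize,
    simulate_posture_sequence,
)
from wormkymo.midline import Midline

PIXEL_SIZE_MM = 0.02
IMAGE_SHAPE = (128, 128)


@pytest.fixture(scope="session")
def mixed_sim():
    """150-s noiseless simulation with omega turns and reversals."""
    cfg = SimulationConfig(
        duration_s=150.0,
        omega_rate_per_s=0.03,
        reversal_rate_per_s=0.02,
        rng_seed=2,
    )
    return simulate_posture_sequence(cfg)


@pytest.fixture(scope="session")
def mixed_stack(mixed_sim):
    return rasterize(mixed_sim, PIXEL_SIZE_MM, IMAGE_SHAPE, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def mixed_midlines(mixed_stack):
    return MidlineExtractor().fit(mixed_stack).transform(mixed_stack)


@pytest.fixture(scope="session")
def forward_sim():
    """Pure forward sine gait, no events."""
    return simulate_posture_sequence(SimulationConfig(duration_s=30.0, rng_seed=0))


def as_midlines(posture):
    """Wrap ground-truth simulator midlines as valid Midline objects."""
    return [Midline(p.copy(), True) for p in posture.midlines]


def straight_midline(k=50, length=1.0, angle=0.0):
    s = np.linspace(0.0, length, k)
    return Midline(
        np.column_stack([s * np.cos(angle), s * np.sin(angle)]), True
    )
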