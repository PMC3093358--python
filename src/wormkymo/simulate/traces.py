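"""Synthetic dual-channel (YFP/CFP) cameleon traces.

Each trace has a donor channel F480 = C * exp(-bleach_rate * t) and an
acceptor channel F535 = F480_clean * R0 * (1 + (response/100) * kernel(t)),
where the response kernel is a rise/decay double exponential normalized to
peak exactly at 1, locked to a temperature-step stimulus at ``onset_s``.
Gaussian noise is added per channel at the requested SNR (channel mean over
noise SD).  The injected peak percent ratio change is recorded per trace as
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SyntheticRatioTrace:
    """One simulated dual-channel trace plus its ground-truth peak."""

    data: pd.DataFrame          # columns: time_s, f535, f480, temperature_c
    true_peak_pct: float
    onset_s: float


def response_kernel(t, onset_s, rise_s, decay_s):
    """Double-exponential response, 0 before onset, peak normalized to 1."""
    t = np.asarray(t, dtype=float)
    if rise_s <= 0 or decay_s <= rise_s:
        raise ValueError("need 0 < rise_s < decay_s")
    dt = np.clip(t - onset_s, 0.0, None)
    k = np.exp(-dt / decay_s) - np.exp(-dt / rise_s)
    # analytic peak of exp(-t/d) - exp(-t/r)
    t_peak = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    out = k / peak
    out[t < onset_s] = 0.0
    return out


def simulate_ratio_traces(
    n_traces: int,
    response_percent: float = 17.0,
    onset_s: float = 30.0,
    kinetics=(2.0, 15.0),
    noise_snr: float = np.inf,
    bleach_rate: float = 0.0,
    seed: int = 0,
    duration_s: float = 120.0,
    sample_rate_hz: float = 5.0,
    f480_mean: float = 1000.0,
    r0: float = 1.5,
    temp_step_c=(20.0, 23.0),
) -> list[SyntheticRatioTrace]:
    """Simulate ``n_traces`` stimulus-locked cameleon traces.

    ``noise_snr`` is channel mean / noise SD (np.inf = noiseless);
    ``bleach_rate`` is the common photobleaching constant in 1/s.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    if bleach_rate < 0:
        raise ValueError("bleach_rate must be >= 0")
    if noise_snr <= 0:
        raise ValueError("noise_snr must be positive (np.inf for noiseless)")
    rise_s, decay_s = kinetics

    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * sample_rate_hz))) / sample_rate_hz
    kernel = response_kernel(t, onset_s, rise_s, decay_s)
    if kernel.max() > 0:
        # renormalize on the sampling grid so the injected peak is exact
        kernel = kernel / kernel.max()
    temperature = np.where(t < onset_s, temp_step_c[0], temp_step_c[1])

    traces = []
    for _ in range(n_traces):
        bleach = np.exp(-bleach_rate * t)
        f480_clean = f480_mean * bleach
        f535_clean = f480_clean * r0 * (1.0 + response_percent / 100.0 * kernel)
        if np.isfinite(noise_snr):
            f480 = f480_clean + rng.normal(0, f480_clean.mean() / noise_snr, t.shape)
            f535 = f535_clean + rng.normal(0, f535_clean.mean() / noise_snr, t.shape)
        else:
            f480, f535 = f480_clean, f535_clean
        traces.append(
            SyntheticRatioTrace(
                data=pd.DataFrame(
                    {
                        "time_s": t,
                        "f535": f535,
                        "f480": f480,
                        "temperature_c": temperature,
                    }
                ),
                true_peak_pct=float(response_percent),
                onset_s=float(onset_s),
            )
        )
    return traces
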