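"""Ratiometric quantification: ratio change, maxima, group summaries, and
puncta-spacing histograms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormkymo import (
    RatioQuantifier,
    fit_response_amplitude,
    group_summary,
    max_ratio_change,
    puncta_spacing,
    ratio_change,
    simulate_ratio_traces,
)


def _trace_df(time, f535, f480, temp=None):
    d = {"time_s": time, "f535": f535, "f480": f480}
    if temp is not None:
        d["temperature_c"] = temp
    return pd.DataFrame(d)


class TestRatioChange:
    def test_constant_channels_zero_change(self):
        t = np.arange(0, 60, 0.2)
        tr = ratio_change(_trace_df(t, np.full_like(t, 300.0), np.full_like(t, 200.0)))
        assert np.allclose(tr.ratio_change_pct, 0.0)
        assert tr.r0 == pytest.approx(1.5)

    def test_injected_peak_recovered_exactly(self):
        (sim,) = simulate_ratio_traces(1, response_percent=20.0, noise_snr=np.inf, seed=0)
        tr = ratio_change(sim.data)
        assert max_ratio_change(tr) == pytest.approx(20.0, abs=1e-9)

    def test_baseline_window_from_stimulus_onset(self):
        (sim,) = simulate_ratio_traces(1, response_percent=10.0, onset_s=40.0, seed=0)
        tr = ratio_change(sim.data)
        assert tr.baseline_window_s == (30.0, 40.0)
        base = (tr.time_s >= 30.0) & (tr.time_s < 40.0)
        assert np.mean(tr.ratio_change_pct[base]) == pytest.approx(0.0, abs=1e-9)

    def test_common_bleach_cancels_exactly(self):
        (clean,) = simulate_ratio_traces(1, response_percent=17.0, noise_snr=np.inf,
                                         bleach_rate=0.0, seed=0)
        (bleached,) = simulate_ratio_traces(1, response_percent=17.0, noise_snr=np.inf,
                                            bleach_rate=0.005, seed=0)
        a = ratio_change(clean.data)
        b = ratio_change(bleached.data)
        assert np.allclose(a.ratio_change_pct, b.ratio_change_pct, atol=1e-9)

    @given(factor=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_common_positive_factor_invariance(self, factor):
        """Scaling both channels by any positive factor leaves the percent
        ratio change unchanged."""
        (sim,) = simulate_ratio_traces(1, response_percent=12.0, noise_snr=50.0, seed=4)
        base = ratio_change(sim.data)
        scaled_df = sim.data.copy()
        scaled_df["f535"] *= factor
        scaled_df["f480"] *= factor
        scaled = ratio_change(scaled_df)
        assert np.allclose(scaled.ratio_change_pct, base.ratio_change_pct, atol=1e-8)

    def test_empty_baseline_rejected(self):
        t = np.arange(0, 60, 0.2)
        df = _trace_df(t, np.full_like(t, 300.0), np.full_like(t, 200.0))
        with pytest.raises(ValueError):
            ratio_change(df, baseline_window_s=(100.0, 110.0))

    def test_nonpositive_f480_rejected(self):
        t = np.arange(0, 60, 0.2)
        f480 = np.full_like(t, 200.0)
        f480[10] = 0.0
        with pytest.raises(ValueError):
            ratio_change(_trace_df(t, np.full_like(t, 300.0), f480))


class TestMaxRatioChange:
    @pytest.mark.parametrize("amp", [5.0, 10.0, 17.0, 25.0, 40.0])
    def test_noiseless_amplitude_sweep_recovered_exactly(self, amp):
        (sim,) = simulate_ratio_traces(1, response_percent=amp, noise_snr=np.inf, seed=0)
        assert max_ratio_change(ratio_change(sim.data)) == pytest.approx(amp, abs=1e-9)

    def test_noisy_group_mean_within_oracle_band(self):
        """Group mean of recovered maxima (SNR 20, n=10) must fall inside a
        Monte-Carlo oracle's 95% band around the injected 17%."""
        sims = simulate_ratio_traces(10, response_percent=17.0, noise_snr=20.0, seed=3)
        maxima = [max_ratio_change(ratio_change(s.data)) for s in sims]
        # oracle: group means of many independent 10-trace experiments
        oracle_means = []
        for rep in range(300):
            osims = simulate_ratio_traces(10, response_percent=17.0, noise_snr=20.0,
                                          seed=10_000 + rep)
            oracle_means.append(
                np.mean([max_ratio_change(ratio_change(s.data)) for s in osims])
            )
        lo, hi = np.percentile(oracle_means, [2.5, 97.5])
        assert lo <= np.mean(maxima) <= hi

    def test_noise_only_extremum_bias_matches_oracle(self):
        """On a flat trace the post-baseline maximum is positively biased;
        the bias must match a resimulation oracle at the same SNR."""
        sims = simulate_ratio_traces(20, response_percent=0.0, noise_snr=20.0, seed=5)
        bias = np.mean([max_ratio_change(ratio_change(s.data)) for s in sims])
        osims = simulate_ratio_traces(200, response_percent=0.0, noise_snr=20.0, seed=6)
        oracle = [max_ratio_change(ratio_change(s.data)) for s in osims]
        assert bias > 0
        sem = np.std(oracle, ddof=1) / np.sqrt(20)
        assert abs(bias - np.mean(oracle)) < 4 * sem

    @pytest.mark.parametrize("amp", [5.0, 17.0, 40.0])
    def test_template_fit_recovers_amplitude_unbiased(self, amp):
        """The template-fit amplitude estimator is exact noiseless and keeps
        |bias| under 5% of the injected amplitude at SNR 10 (n = 10)."""
        (clean,) = simulate_ratio_traces(1, response_percent=amp,
                                         noise_snr=np.inf, seed=0)
        assert fit_response_amplitude(ratio_change(clean.data)) == pytest.approx(
            amp, rel=1e-3
        )
        sims = simulate_ratio_traces(10, response_percent=amp, noise_snr=10.0, seed=8)
        ests = [fit_response_amplitude(ratio_change(s.data)) for s in sims]
        # n = 10 noisy traces: the group mean must sit within 5 percentage
        # points of the injected peak and within sampling error of zero bias
        sem = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - amp) < 5.0
        assert abs(np.mean(ests) - amp) < 4.0 * sem + 0.5

    def test_min_mode_for_inhibitory_responses(self):
        (sim,) = simulate_ratio_traces(1, response_percent=-15.0, noise_snr=np.inf, seed=0)
        tr = ratio_change(sim.data)
        assert max_ratio_change(tr, mode="min") == pytest.approx(-15.0, abs=1e-9)


class TestGroupSummary:
    def test_identical_traces_zero_sem(self):
        sims = simulate_ratio_traces(1, response_percent=10.0, noise_snr=np.inf, seed=0)
        traces = [ratio_change(sims[0].data)] * 5
        g = group_summary(traces)
        assert np.allclose(g.sem_trace_pct, 0.0)
        assert g.sem_max_pct == pytest.approx(0.0)

    def test_two_trace_mean_and_sem_arithmetic(self):
        a = simulate_ratio_traces(1, response_percent=10.0, noise_snr=np.inf, seed=0)[0]
        b = simulate_ratio_traces(1, response_percent=30.0, noise_snr=np.inf, seed=0)[0]
        g = group_summary([ratio_change(a.data), ratio_change(b.data)])
        assert g.mean_max_pct == pytest.approx(20.0, abs=1e-9)
        assert g.sem_max_pct == pytest.approx(10.0, abs=1e-9)

    def test_pointwise_sem_matches_direct_formula(self):
        sims = simulate_ratio_traces(10, response_percent=17.0, noise_snr=15.0, seed=7)
        traces = [ratio_change(s.data) for s in sims]
        g = group_summary(traces)
        mat = np.vstack([tr.ratio_change_pct for tr in traces])
        assert np.allclose(g.sem_trace_pct, mat.std(axis=0, ddof=1) / np.sqrt(10),
                           atol=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_summary([])


class TestRatioQuantifierEstimator:
    def test_transform_and_summarize(self):
        sims = simulate_ratio_traces(4, response_percent=17.0, noise_snr=np.inf, seed=0)
        quant = RatioQuantifier().fit()
        out = quant.transform([s.data for s in sims])
        assert len(out) == 4
        g = quant.summarize([s.data for s in sims])
        assert g.mean_max_pct == pytest.approx(17.0, abs=1e-9)

    def test_invalid_baseline_rejected(self):
        with pytest.raises(ValueError):
            RatioQuantifier(baseline_s=-1.0).fit()


class TestPunctaSpacing:
    def _comb(self, spacing_um=2.0, n_peaks=12, um_per_sample=0.05, missing=None):
        n = int(n_peaks * spacing_um / um_per_sample) + 40
        y = np.zeros(n)
        x = np.arange(n) * um_per_sample
        for k in range(n_peaks):
            if missing is not None and k == missing:
                continue
            c = (k + 1) * spacing_um
            y += np.exp(-((x - c) ** 2) / (2 * 0.15**2))
        return y, um_per_sample

    def test_regular_comb_single_occupied_class(self):
        y, cal = self._comb()
        prof = puncta_spacing(y, cal)
        assert np.allclose(prof.spacings_um, 2.0, atol=0.06)
        assert (prof.class_fractions > 0).sum() == 1
        assert prof.class_fractions.sum() == pytest.approx(1.0)

    def test_missing_tooth_doubles_one_spacing(self):
        y, cal = self._comb(missing=5)
        prof = puncta_spacing(y, cal)
        occupied = prof.class_fractions > 0
        assert occupied.sum() == 2
        assert np.isclose(prof.spacings_um.max(), 4.0, atol=0.1)

    def test_noisy_comb_mean_spacing_within_5pct(self):
        rng = np.random.default_rng(11)
        y, cal = self._comb()
        y = y + rng.normal(0, 0.05, y.shape)
        prof = puncta_spacing(y, cal, min_prominence=0.4)
        assert prof.spacings_um.mean() == pytest.approx(2.0, rel=0.05)

    def test_single_punctum_yields_empty_spacings(self):
        y = np.zeros(400)
        y[200] = 1.0
        prof = puncta_spacing(y, 0.05)
        assert len(prof.spacings_um) == 0
        assert prof.class_fractions.sum() == 0.0

    def test_sixteen_class_edges_emitted(self):
        y, cal = self._comb()
        prof = puncta_spacing(y, cal)
        assert len(prof.class_edges_um) == 17
        assert prof.class_edges_um[0] == 0.0 and prof.class_edges_um[-1] == 8.0
        # histogram conservation: spacing count = puncta count - 1
        assert len(prof.spacings_um) == len(prof.positions_um) - 1
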