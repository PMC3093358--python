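"""Tests of the synthetic-data generators: posture sequences, rasterized
video, plate tracks, and fluorescence traces."""

import numpy as np
import pytest

from wormkymo import (
    FORWARD,
    OMEGA,
    SimulationConfig,
    rasterize,
    simulate_plate_track,
    simulate_posture_sequence,
    simulate_ratio_traces,
)
from wormkymo.simulate.posture import PostureSequence
from wormkymo.simulate.raster import tube_area_mm2

from conftest import straight_midline


class TestPostureSequence:
    def test_no_events_gives_pure_forward_run_with_net_displacement(self):
        ps = simulate_posture_sequence(SimulationConfig(duration_s=60.0))
        assert np.all(ps.true_state == FORWARD)
        disp = np.hypot(*(ps.midlines[-1].mean(0) - ps.midlines[0].mean(0)))
        assert disp > 0.5  # 0.15 mm/s for 60 s, minus undulation wobble

    def test_identical_seed_is_bit_identical(self):
        cfg = SimulationConfig(duration_s=20.0, omega_rate_per_s=0.05,
                               reversal_rate_per_s=0.03, rng_seed=7)
        a = simulate_posture_sequence(cfg)
        b = simulate_posture_sequence(cfg)
        assert np.array_equal(a.midlines, b.midlines)
        assert np.array_equal(a.true_state, b.true_state)

    def test_arc_length_spacing_constant(self):
        ps = simulate_posture_sequence(
            SimulationConfig(duration_s=30.0, omega_rate_per_s=0.1, rng_seed=1)
        )
        seg = np.hypot(*np.rollaxis(np.diff(ps.midlines, axis=1), 2))
        rel = np.abs(seg / seg.mean() - 1.0)
        assert rel.max() < 1e-6  # inextensible worm, equal spacings

    def test_inter_omega_intervals_exponential_vs_monte_carlo_oracle(self):
        """Empirical mean inter-omega interval must sit inside the 95% CI of
        an exponential-gap Monte-Carlo oracle run at the same sample size."""
        rate, duration = 0.03, 1000.0
        ps = simulate_posture_sequence(
            SimulationConfig(duration_s=duration, omega_rate_per_s=rate,
                             omega_duration_s=2.0, rng_seed=1)
        )
        onsets = ps.omega_onsets_s()
        gaps = np.diff(onsets)
        n = len(gaps)
        assert n >= 10
        # oracle: direct Monte-Carlo of n exponential gaps
        rng = np.random.default_rng(12345)
        means = rng.exponential(1.0 / rate, size=(10_000, n)).mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
        assert lo <= gaps.mean() <= hi

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_poisson_event_count_bound(self, seed):
        rate, duration = 0.05, 600.0
        ps = simulate_posture_sequence(
            SimulationConfig(duration_s=duration, omega_rate_per_s=rate,
                             rng_seed=seed)
        )
        count = len(ps.omega_intervals_s)
        assert abs(count - rate * duration) <= 3.0 * np.sqrt(rate * duration)

    def test_omega_pose_brings_head_within_one_body_width(self):
        from scipy.spatial.distance import pdist, squareform

        ps = simulate_posture_sequence(
            SimulationConfig(duration_s=40.0, omega_rate_per_s=0.1, rng_seed=3)
        )
        assert ps.omega_intervals_s
        for s, e in ps.omega_intervals_s:
            i = int((s + e) / 2 * ps.config.frame_rate_hz)
            pts = ps.midlines[i]
            K = len(pts)
            d = squareform(pdist(pts))
            sep = np.abs(np.subtract.outer(np.arange(K), np.arange(K))) / (K - 1)
            assert d[sep > 0.25].min() < ps.config.body_length_mm / 12.0

    def test_state_labels_cover_all_frames(self):
        ps = simulate_posture_sequence(
            SimulationConfig(duration_s=60.0, omega_rate_per_s=0.05,
                             reversal_rate_per_s=0.05, rng_seed=4)
        )
        assert set(np.unique(ps.true_state)) <= {"FORWARD", "BACKWARD", "OMEGA"}
        assert len(ps.true_state) == ps.n_frames

    @pytest.mark.parametrize(
        "bad",
        [
            {"duration_s": -1.0},
            {"frame_rate_hz": 0.0},
            {"omega_rate_per_s": -0.1},
            {"n_midline_points": 5},
            {"wave_frequency_hz": float("nan")},
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_posture_sequence(SimulationConfig(**bad))


class TestRasterize:
    def _single_frame(self, midline, px=0.02, shape=(128, 128)):
        cfg = SimulationConfig()
        ps = PostureSequence(
            times=np.array([0.0]),
            midlines=midline.points[None],
            true_state=np.array([FORWARD]),
            config=cfg,
        )
        return rasterize(ps, px, shape)

    def test_straight_worm_major_axis_matches_body_length(self):
        px = 0.02
        stack = self._single_frame(straight_midline(), px=px)
        fg = stack.frames[0] > 0.5
        cols = np.where(fg.any(axis=0))[0]
        extent_px = cols.max() - cols.min() + 1
        assert abs(extent_px - 1.0 / px) <= 2 + 2  # tube caps extend ~1 px/end

    def test_foreground_area_matches_analytic_tube_model(self):
        px = 0.02
        stack = self._single_frame(straight_midline(), px=px)
        area = (stack.frames[0] > 0.5).sum() * px**2
        assert area == pytest.approx(tube_area_mm2(1.0), rel=0.05)

    def test_area_stable_across_frames(self, forward_sim):
        stack = rasterize(forward_sim, 0.02, (128, 128))
        areas = (stack.frames > 0.5).sum(axis=(1, 2))
        assert areas.std() / areas.mean() < 0.05

    def test_empty_posture_rejected(self):
        cfg = SimulationConfig()
        empty = PostureSequence(
            times=np.empty(0), midlines=np.empty((0, 50, 2)),
            true_state=np.empty(0, dtype="<U8"), config=cfg,
        )
        with pytest.raises(ValueError):
            rasterize(empty, 0.02, (128, 128))

    def test_worm_out_of_frame_names_offending_frame(self):
        with pytest.raises(ValueError, match="frame 0"):
            self._single_frame(straight_midline(length=4.0), px=0.02, shape=(64, 64))

    def test_nonpositive_pixel_size_rejected(self, forward_sim):
        with pytest.raises(ValueError):
            rasterize(forward_sim, 0.0, (128, 128))


class TestPlateTracks:
    def test_stay_center_occupies_cold_zone(self):
        track = simulate_plate_track("thermotaxis", {"archetype": "stay-center"}, seed=1)
        r_cold = track.gradient.radius_at(18.5)
        frac = np.mean(track.radius_mm <= r_cold)
        assert frac >= 0.90

    def test_zero_speed_track_is_constant(self):
        track = simulate_plate_track(
            "thermotaxis", {"archetype": "stay-center", "speed_mm_s": 0.0}, seed=0
        )
        assert np.allclose(track.x_mm, track.x_mm[0])
        assert np.allclose(track.y_mm, track.y_mm[0])

    def test_same_seed_identical(self):
        a = simulate_plate_track("nacl", {"archetype": "approach-peak-k-times"}, seed=5)
        b = simulate_plate_track("nacl", {"archetype": "approach-peak-k-times"}, seed=5)
        assert np.array_equal(a.x_mm, b.x_mm) and np.array_equal(a.y_mm, b.y_mm)

    def test_track_confined_to_plate(self):
        track = simulate_plate_track("thermotaxis", {"archetype": "stay-periphery"}, seed=2)
        assert np.all(track.radius_mm <= track.plate_radius_mm + 1e-9)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            simulate_plate_track("phototaxis", {}, seed=0)


class TestRatioTraceSim:
    def test_null_response_constant_ratio(self):
        (tr,) = simulate_ratio_traces(1, response_percent=0.0, noise_snr=np.inf,
                                      bleach_rate=0.0, seed=0)
        ratio = tr.data["f535"] / tr.data["f480"]
        assert np.allclose(ratio, ratio.iloc[0])
        assert tr.true_peak_pct == 0.0

    def test_injected_peak_exact_when_noiseless(self):
        (tr,) = simulate_ratio_traces(1, response_percent=20.0, noise_snr=np.inf, seed=0)
        ratio = (tr.data["f535"] / tr.data["f480"]).to_numpy()
        r0 = ratio[tr.data["time_s"] < tr.onset_s].mean()
        assert np.max((ratio - r0) / r0 * 100) == pytest.approx(20.0, abs=1e-9)

    def test_noisy_peaks_scatter_matches_monte_carlo_oracle(self):
        """Per-trace recovered peaks at SNR 20 must scatter like a fresh
        Monte-Carlo resimulation at the same SNR."""
        traces = simulate_ratio_traces(10, response_percent=17.0, noise_snr=20.0, seed=3)
        peaks = []
        for tr in traces:
            ratio = (tr.data["f535"] / tr.data["f480"]).to_numpy()
            r0 = ratio[tr.data["time_s"] < tr.onset_s].mean()
            peaks.append(np.max((ratio - r0) / r0 * 100))
        # oracle: many independent resimulations of the same measurement
        oracle = simulate_ratio_traces(400, response_percent=17.0, noise_snr=20.0, seed=991)
        opeaks = []
        for tr in oracle:
            ratio = (tr.data["f535"] / tr.data["f480"]).to_numpy()
            r0 = ratio[tr.data["time_s"] < tr.onset_s].mean()
            opeaks.append(np.max((ratio - r0) / r0 * 100))
        lo, hi = np.percentile(opeaks, [0.5, 99.5])
        assert lo <= np.min(peaks) and np.max(peaks) <= hi
        # and the group mean is consistent with the oracle mean
        sem = np.std(opeaks, ddof=1) / np.sqrt(len(peaks))
        assert abs(np.mean(peaks) - np.mean(opeaks)) < 4 * sem

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_ratio_traces(1, noise_snr=-5.0)
        with pytest.raises(ValueError):
            simulate_ratio_traces(1, bleach_rate=-0.1)
        with pytest.raises(ValueError):
            simulate_ratio_traces(0)
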