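"""Generator correctness: geometry, rendering physics, schedules, presets."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

import calwave as cw
from calwave.synthetic import (
    draw_spontaneous_events,
    draw_wave_events,
    transient_kernel,
)


class TestMonolayer:
    def test_same_seed_is_deterministic(self):
        a = cw.generate_monolayer(cw.MonolayerSpec(seed=4))
        b = cw.generate_monolayer(cw.MonolayerSpec(seed=4))
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_centers_in_field_and_separated(self):
        spec = cw.MonolayerSpec(
            field_size=(512, 512), pixel_size_um=0.5, cell_radius_um=8.0,
            packing=2.5, seed=2,
        )
        cells = cw.generate_monolayer(spec)
        assert cells.n_cells > 100
        h, w = cells.field_size
        assert (cells.centers[:, 0] >= 0).all() and (
            cells.centers[:, 0] <= w - 1
        ).all()
        assert (cells.centers[:, 1] >= 0).all() and (
            cells.centers[:, 1] <= h - 1
        ).all()
        # brute-force pairwise separation in physical units
        assert pdist(cells.centers_um).min() > spec.cell_radius_um

    def test_field_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            cw.generate_monolayer(cw.MonolayerSpec(field_size=(1, 1)))

    def test_packing_below_two_rejected(self):
        with pytest.raises(ValueError):
            cw.MonolayerSpec(packing=1.5)


class TestTransientKernel:
    def test_peaks_at_zero_with_unit_height(self):
        t = np.linspace(-20, 60, 4001)
        k = transient_kernel(t, 4.0, 15.0)
        assert k.max() == pytest.approx(1.0, abs=1e-9)
        assert abs(t[k.argmax()]) < 0.03
        assert (k[t < -8] == 0).all()

    def test_invalid_time_constants(self):
        with pytest.raises(ValueError):
            transient_kernel(np.zeros(3), 5.0, 5.0)


class TestRenderMovie:
    def test_quiescent_noise_free_normalizes_to_one(self, small_monolayer,
                                                    quiet_movie):
        movie, events, kin = quiet_movie
        assert len(events) == 0
        traces = cw.extract_traces(movie, small_monolayer, frame_rate=2.0)
        processed, peaks = cw.process_traceset(
            traces, background=kin.background
        )
        assert len(peaks) == 0
        assert np.abs(processed - 1.0).max() < 1e-3

    def test_bleach_fraction_reflected_in_raw_trace(self, small_monolayer):
        kin = cw.KineticsSpec(
            n_frames=100, noise_sd=0.0, baseline_cv=0.0, bleach_fraction=0.2,
            background=0.0, responsive_fraction_by_zone={"control": 0.0},
        )
        movie, _ = cw.render_movie(small_monolayer, kin, seed=0)
        traces = cw.extract_traces(movie, small_monolayer, frame_rate=2.0)
        ratio = traces.traces[:, -1] / traces.traces[:, 0]
        np.testing.assert_allclose(ratio, 0.8, atol=0.01)

    def test_single_injected_transient_recovered_at_amplitude(self):
        # one cell, one 1.3-amplitude transient, no noise: the processed
        # trace must return to 1.3 +/- 0.01 at the injected peak frame
        cells = cw.CellMap(np.array([[32.0, 32.0]]), 7.0, 1.0, (64, 64))
        kin = cw.KineticsSpec(
            n_frames=300, noise_sd=0.0, baseline_cv=0.0, bleach_fraction=0.1,
            background=0.0, transient_amplitude=1.3, transient_amplitude_sd=0.0,
            responsive_fraction_by_zone={"control": 1.0},
            event_window_s=(50.0, 50.0001), mean_extra_events=0.0,
        )
        movie, events = cw.render_movie(cells, kin, seed=1)
        assert len(events) == 1
        traces = cw.extract_traces(movie, cells, frame_rate=2.0)
        processed, peaks = cw.process_traceset(traces, background=0.0)
        assert len(peaks) == 1
        assert peaks["amplitude"].iloc[0] == pytest.approx(1.3, abs=0.01)
        assert abs(
            int(peaks["peak_frame"].iloc[0]) - int(events["event_frame"].iloc[0])
        ) <= 1

    def test_bit_identical_for_same_seed(self, small_monolayer):
        kin = cw.KineticsSpec(n_frames=40)
        m1, e1 = cw.render_movie(small_monolayer, kin, seed=9)
        m2, e2 = cw.render_movie(small_monolayer, kin, seed=9)
        np.testing.assert_array_equal(m1, m2)
        pd.testing.assert_frame_equal(e1, e2)

    def test_wave_origin_outside_field_raises(self, small_monolayer):
        kin = cw.KineticsSpec(n_frames=40)
        wave = cw.WaveSpec(origin_xy=(500.0, 10.0), max_radius_um=30.0)
        with pytest.raises(ValueError, match="origin"):
            cw.render_movie(small_monolayer, kin, wave=wave, seed=0)


class TestEventStatistics:
    def test_responsive_fraction_matches_configuration(self, small_monolayer):
        # ground-truth fidelity: over 20 seeds the empirical responsive
        # fraction stays within 3 binomial SEs of the configured probability
        p_true = 0.3
        kin = cw.KineticsSpec(
            n_frames=600, responsive_fraction_by_zone={"control": p_true}
        )
        n_resp, n_tot = 0, 0
        for seed in range(20):
            ev = draw_spontaneous_events(
                small_monolayer, kin, np.random.default_rng(seed)
            )
            n_resp += ev["cell_id"].nunique()
            n_tot += small_monolayer.n_cells
        se = np.sqrt(p_true * (1 - p_true) / n_tot)
        assert abs(n_resp / n_tot - p_true) < 3 * se

    def test_wave_peak_times_nondecreasing_with_hops(self, small_monolayer):
        kin = cw.KineticsSpec(n_frames=600)
        wave = cw.WaveSpec(
            origin_xy=(64.0, 64.0), max_radius_um=60.0, stim_time_s=40.0
        )
        ev = draw_wave_events(
            small_monolayer, wave, kin, np.random.default_rng(0)
        )
        assert len(ev) > 5
        d = np.hypot(ev["x_px"] - 64.0, ev["y_px"] - 64.0)
        order = np.argsort(d.to_numpy())
        times = ev["event_time_s"].to_numpy()[order]
        assert (np.diff(times) >= 0).all()


class TestWoundSeries:
    def test_linear_schedule_exact(self):
        mask = np.zeros((40, 60), dtype=np.uint8)
        mask[:20, :50] = 1  # 1000 px
        spec = cw.WoundClosureSpec(
            initial_wound_mask=mask, closure_time_h=20.0, frame_interval_h=1.0
        )
        series = cw.render_wound_series(spec)
        areas = cw.wound_area_series(series)
        assert areas[0] == 1000
        assert areas[10] == 500  # linear: half the area at half the time
        assert areas[20] == 0 and (areas[:20] > 0).all()

    def test_first_zero_frame_at_closure_time(self):
        mask = np.ones((30, 30), dtype=np.uint8)
        spec = cw.WoundClosureSpec(
            initial_wound_mask=mask, closure_time_h=49.0, frame_interval_h=1.0
        )
        series = cw.render_wound_series(spec)
        areas = cw.wound_area_series(series)
        assert series.n_frames == 50
        assert series.timestamps_h[49] == 49.0
        assert areas[49] == 0 and (areas[:49] > 0).all()

    def test_stalled_profile_never_closes(self):
        mask = np.ones((20, 20), dtype=np.uint8)
        spec = cw.WoundClosureSpec(
            initial_wound_mask=mask, closure_time_h=10.0,
            closure_profile="stalled",
        )
        areas = cw.wound_area_series(cw.render_wound_series(spec))
        assert (areas > 0).all()

    def test_area_non_increasing_for_linear(self):
        mask = np.ones((25, 25), dtype=np.uint8)
        spec = cw.WoundClosureSpec(initial_wound_mask=mask, closure_time_h=7.0)
        areas = cw.wound_area_series(cw.render_wound_series(spec))
        assert (np.diff(areas) <= 0).all()

    def test_invalid_specs(self):
        mask = np.ones((5, 5), dtype=np.uint8)
        with pytest.raises(ValueError):
            cw.WoundClosureSpec(initial_wound_mask=mask, closure_time_h=0.0)
        with pytest.raises(ValueError, match="empty"):
            cw.render_wound_series(
                cw.WoundClosureSpec(
                    initial_wound_mask=np.zeros((5, 5)), closure_time_h=5.0
                )
            )


class TestPresets:
    def test_healing_presets_carry_closure_times(self):
        assert cw.preset("healing-9d").closure_time_h == 20
        assert cw.preset("healing-28d").closure_time_h == 49

    def test_wave_presets_carry_condition_means(self):
        assert cw.preset("28d7d-wave-wounded").wave.mean_cells == 79
        assert cw.preset("28d7d-wave-control").wave.mean_cells == 17

    def test_rc_presets_carry_condition_fractions(self):
        k = cw.preset("9d15min").kinetics
        assert k.responsive_fraction_by_zone["area1"] == pytest.approx(0.332)
        k2 = cw.preset("28d7d").kinetics
        assert k2.responsive_fraction_by_zone["wound"] == pytest.approx(0.197)
        assert k2.responsive_fraction_by_zone["control"] == pytest.approx(0.387)

    def test_unknown_preset_lists_available(self):
        with pytest.raises(ValueError, match="available"):
            cw.preset("nonexistent")

    def test_recording_frame_rate_and_length(self):
        # recordings are 2 frames/s for at least 5 min (600 frames)
        k = cw.preset("9d15min").kinetics
        assert k.frame_rate == 2.0 and k.n_frames >= 600
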