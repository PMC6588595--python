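"""Acrophase maps, line scans, ROI series, calcium-transient detection."""

import numpy as np
import pytest

from scnburst import (
    ConfigurationError,
    GenConfig,
    ImageStack,
    burst_ca_coincidence,
    detect_bursts,
    detect_ca_spikes,
    gen_burst_schedule,
    gen_calcium_traces,
    gen_image_stack,
    gen_spike_trains,
    bin_spikes,
    line_scan,
    pixel_acrophase_map,
    rayleigh_stats,
    roi_series,
)
from scnburst.containers import BurstCatalog, BurstEvent
from scnburst.imaging import CalciumEvent, CalciumEventList


def model_stack(phi_h, tau_h=24.0, n_frames=72, mesor=100.0, amp=50.0, t0_s=0.0):
    """Noiseless cosine stack with per-pixel acrophase map ``phi_h`` (H, W)."""
    t = np.arange(n_frames) * 3600.0 + t0_s
    frames = mesor + amp * np.cos(
        2 * np.pi * (t[:, None, None] / 3600.0 - phi_h[None]) / tau_h
    )
    return ImageStack(frames=frames, frame_interval_s=3600.0, pixel_size_um=4.3, t0_s=t0_s)


class TestAcrophaseMap:
    def test_zero_dispersion_gives_flat_relative_map_and_r_one(self):
        cfg = GenConfig(duration_h=3 * 23.7, img_phase_sd_h=0.0, img_noise_sd=0.0, seed=1)
        amap = pixel_acrophase_map(gen_image_stack(cfg), cfg.img_period_h)
        assert amap.mask.all()
        np.testing.assert_allclose(amap.relative_h, 0.0, atol=1e-6)
        assert amap.rayleigh_r() == pytest.approx(1.0)

    def test_dorsoventral_gradient_recovered(self):
        g = 0.25  # h per row, dorsal (row 0) earliest
        rows = np.arange(16)
        phi = 6.0 + g * rows[:, None] + np.zeros((1, 12))
        amap = pixel_acrophase_map(model_stack(phi), 24.0)
        row_means = amap.acrophase_h.mean(axis=1)
        slope = np.polyfit(rows, row_means, 1)[0]
        assert slope == pytest.approx(g, rel=0.02)

    def test_rayleigh_r_consistent_with_phase_list(self):
        cfg = GenConfig(duration_h=3 * 23.7, img_phase_sd_h=0.5, seed=2)
        amap = pixel_acrophase_map(gen_image_stack(cfg), cfg.img_period_h)
        r_direct = rayleigh_stats(amap.masked_phases(), cfg.img_period_h).r
        assert amap.rayleigh_r() == pytest.approx(r_direct)

    def test_time_shift_equivariance(self):
        phi = np.random.default_rng(0).uniform(0, 24, (8, 8))
        delta_h = 5.0
        m0 = pixel_acrophase_map(model_stack(phi), 24.0)
        m1 = pixel_acrophase_map(model_stack(phi, t0_s=delta_h * 3600.0), 24.0)
        diff = (m1.acrophase_h - m0.acrophase_h) % 24.0
        np.testing.assert_allclose(np.where(diff > 23.9, diff - 24, diff), 0.0, atol=1e-6)
        np.testing.assert_allclose(m1.relative_h, m0.relative_h, atol=1e-6)

    def test_nonrhythmic_stack_rejected(self):
        frames = np.ones((10, 4, 4))
        stack = ImageStack(frames, 3600.0, 4.3)
        with pytest.raises(ConfigurationError):
            pixel_acrophase_map(stack, 24.0)


class TestLineScan:
    def test_uniform_stack_gives_constant_kymograph(self):
        stack = ImageStack(np.full((5, 8, 8), 3.0), 1.0, 1.0)
        kymo = line_scan(stack, (0, 4), (7, 4))
        np.testing.assert_allclose(kymo, 3.0)
        assert kymo.shape == (8, 5)

    def test_single_row_line_equals_row_series(self):
        rng = np.random.default_rng(1)
        stack = ImageStack(rng.random((6, 5, 9)), 1.0, 1.0)
        kymo = line_scan(stack, (2, 0), (2, 8))
        np.testing.assert_allclose(kymo, stack.frames[:, 2, :].T)

    def test_synchronized_transient_spans_all_positions_simultaneously(self):
        # global calcium transient at 10 fps: vertical stripe in the kymograph
        frames = np.ones((50, 16, 16))
        frames[20] = 12.0  # slice-wide flash
        stack = ImageStack(frames, 0.1, 1.0)
        kymo = line_scan(stack, (0, 8), (15, 8))
        peaks = np.argmax(kymo, axis=1)
        assert np.ptp(peaks) < 1  # peak-time spread below one frame

    def test_out_of_bounds_rejected(self):
        stack = ImageStack(np.zeros((3, 4, 4)), 1.0, 1.0)
        with pytest.raises(ConfigurationError):
            line_scan(stack, (0, 0), (5, 0))


class TestRoiSeries:
    def test_whole_frame_mask_on_uniform_stack(self):
        frames = np.arange(6, dtype=float)[:, None, None] * np.ones((6, 4, 4))
        stack = ImageStack(frames, 1.0, 1.0)
        np.testing.assert_allclose(roi_series(stack, np.ones((4, 4), bool)), np.arange(6))

    def test_union_of_equal_area_rois_averages(self):
        frames = np.zeros((4, 2, 2))
        frames[:, 0, 0] = 2.0
        frames[:, 1, 1] = 6.0
        stack = ImageStack(frames, 1.0, 1.0)
        m = np.zeros((2, 2), bool)
        m[0, 0] = m[1, 1] = True
        np.testing.assert_allclose(roi_series(stack, m), 4.0)

    def test_empty_mask_rejected(self):
        stack = ImageStack(np.zeros((3, 4, 4)), 1.0, 1.0)
        with pytest.raises(ConfigurationError):
            roi_series(stack, np.zeros((4, 4), bool))

    def test_cosinor_period_recovery_from_roi(self):
        from scnburst import cosinor_fit

        cfg = GenConfig(duration_h=5 * 23.7, img_phase_sd_h=0.2, seed=3)
        stack = gen_image_stack(cfg)
        trace = roi_series(stack, np.ones(stack.shape, bool))
        fit = cosinor_fit(stack.frame_times_s() / 3600.0, trace, tau_h=None)
        assert fit.period_h == pytest.approx(cfg.img_period_h, abs=0.1)


class TestCalciumDetection:
    def test_noiseless_circadian_baseline_has_no_events(self):
        t = np.arange(0, 1800, 3.0)
        trace = 100 + 20 * np.cos(2 * np.pi * t / 86400.0)
        assert len(detect_ca_spikes(trace, 3.0)) == 0

    def test_five_scheduled_transients_counted_exactly_at_default_snr(self):
        # generator default transient amplitude (20x noise SD), 20 seeds
        for seed in range(20):
            cfg = GenConfig(
                preset="gaba_deficient", duration_h=600 / 3600,
                burst_interval_s=(120.0, 120.0), seed=seed,
            )
            sch = gen_burst_schedule(cfg)
            ca = gen_calcium_traces(cfg, sch, n_traces=1)
            ev = detect_ca_spikes(next(iter(ca.traces.values())), 3.0)
            assert len(ev) == len(sch) == 5

    def test_sensitivity_at_5x_noise_floor(self):
        # amplitude exactly at the 5x noise-SD floor: most events recovered
        counts = []
        for seed in range(20):
            cfg = GenConfig(
                preset="gaba_deficient", duration_h=600 / 3600,
                burst_interval_s=(120.0, 120.0),
                ca_transient_amp=5 * 2.0, ca_noise_sd=2.0, seed=seed,
            )
            sch = gen_burst_schedule(cfg)
            ca = gen_calcium_traces(cfg, sch, n_traces=1)
            counts.append(len(detect_ca_spikes(next(iter(ca.traces.values())), 3.0)))
        assert sum(counts) >= 0.85 * 20 * 5
        assert sum(counts) <= 20 * 5 + 2

    def test_amplitude_estimate_close_at_high_snr(self):
        cfg = GenConfig(preset="gaba_deficient", duration_h=0.5, ca_noise_sd=0.5, seed=4)
        sch = gen_burst_schedule(cfg)
        ca = gen_calcium_traces(cfg, sch, n_traces=1)
        ev = detect_ca_spikes(next(iter(ca.traces.values())), 3.0)
        injected_dff = cfg.ca_transient_amp / cfg.ca_mesor
        amps = np.array([e.amplitude_dff for e in ev.events])
        # sampling can catch the transient up to one frame after onset
        assert np.all(np.abs(amps / injected_dff - 1.0) < 0.25)
        assert np.median(np.abs(amps / injected_dff - 1.0)) < 0.2

    def test_false_positive_rate_below_one_per_day(self):
        # pure-noise traces, pooled over 30 simulated days
        n_days, events = 30, 0
        for seed in range(n_days):
            rng = np.random.default_rng(seed)
            trace = 100 + rng.normal(0, 2.0, size=28800)  # one day at 3 s
            events += len(detect_ca_spikes(trace, 3.0))
        assert events / n_days < 1.0

    def test_zero_variance_trace_gives_empty_list(self):
        assert len(detect_ca_spikes(np.full(100, 7.0), 3.0)) == 0


class TestCoincidence:
    def cat(self, starts):
        evs = [BurstEvent(s, s + 5.0, 60.0) for s in starts]
        return BurstCatalog(35.0, {"e00": evs}, evs)

    def evs(self, times):
        return CalciumEventList([CalciumEvent(t, 1.0, 5.0) for t in times])

    def test_identical_schedules_give_unit_fractions(self):
        co = burst_ca_coincidence(self.evs([10, 150, 300]), self.cat([10, 150, 300]))
        assert co.frac_ca_near_burst == 1.0 and co.frac_burst_near_ca == 1.0

    def test_disjoint_schedules_give_zero(self):
        co = burst_ca_coincidence(self.evs([10, 150]), self.cat([50, 250]), tol_s=2.0)
        assert co.frac_ca_near_burst == 0.0 and co.frac_burst_near_ca == 0.0

    def test_empty_list_gives_absent_fractions(self):
        co = burst_ca_coincidence(self.evs([]), self.cat([10.0]))
        assert co.frac_ca_near_burst is None and co.frac_burst_near_ca is None

    def test_generator_coupled_recordings_coincide(self):
        cfg = GenConfig(preset="gaba_deficient", n_electrodes=2, duration_h=0.5, seed=5)
        sch = gen_burst_schedule(cfg)
        catalog = detect_bursts(bin_spikes(gen_spike_trains(cfg, sch), 0.1))
        ca = gen_calcium_traces(cfg, sch, n_traces=1)
        ev = detect_ca_spikes(next(iter(ca.traces.values())), cfg.ca_frame_interval_s)
        co = burst_ca_coincidence(ev, catalog, tol_s=cfg.ca_frame_interval_s)
        assert co.frac_ca_near_burst >= 0.9
        assert co.frac_burst_near_ca >= 0.9
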