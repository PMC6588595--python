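"""Burst statistics: binning, bin-ratio distribution, detection, bands, synchrony."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scnburst import (
    ConfigurationError,
    CTAnchor,
    GenConfig,
    RateSeriesSet,
    SpikeTrainSet,
    band_decomposition,
    bin_ratio_distribution,
    bin_spikes,
    burst_phase_profile,
    detect_bursts,
    gen_burst_schedule,
    gen_spike_trains,
    synchrony_matrix,
)
from scnburst.containers import BurstCatalog, BurstEvent


def trains_of(spikes_s, duration_s):
    return SpikeTrainSet(
        electrodes=["e00"], spikes={"e00": np.asarray(spikes_s, float)},
        duration_s=duration_s,
    )


def rates_of(values, bin_width_s=0.1, **kw):
    return RateSeriesSet(bin_width_s=bin_width_s, rates={"e00": np.asarray(values, float)}, **kw)


class TestBinSpikes:
    def test_ten_minute_record_has_6000_hundred_ms_bins(self):
        fine = bin_spikes(trains_of([1.0], 600.0), 0.1)
        assert fine.n_bins == 6000

    def test_no_spikes_gives_zero_rates(self):
        fine = bin_spikes(trains_of([], 10.0), 0.1)
        assert np.all(fine.rates["e00"] == 0)

    def test_four_spikes_in_one_bin_is_40hz(self):
        fine = bin_spikes(trains_of([0.51, 0.52, 0.55, 0.58], 1.0), 0.1)
        assert fine.rates["e00"][5] == pytest.approx(40.0)
        assert fine.rates["e00"].sum() == pytest.approx(40.0)

    def test_partial_trailing_bin_dropped(self):
        fine = bin_spikes(trains_of([0.95], 0.95), 0.1)
        assert fine.n_bins == 9

    def test_empty_electrode_set_rejected(self):
        with pytest.raises(ConfigurationError):
            SpikeTrainSet(electrodes=[], spikes={}, duration_s=1.0)


class TestBinRatio:
    def test_all_zero_rates_land_in_lowest_class(self):
        d = bin_ratio_distribution(rates_of(np.zeros(6000)))
        assert d.bin_fraction_pct[0] == pytest.approx(100.0)
        assert d.frac_above_35hz_pct == 0.0
        assert d.n_bins_total == 6000

    def test_fractions_sum_to_100(self):
        rng = np.random.default_rng(0)
        d = bin_ratio_distribution(rates_of(rng.uniform(0, 120, 5000)))
        assert d.bin_fraction_pct.sum() == pytest.approx(100.0)

    def test_window_shorter_than_bin_rejected(self):
        with pytest.raises(ConfigurationError):
            bin_ratio_distribution(rates_of(np.zeros(100)), window_s=(0.0, 0.05))


def brute_force_events(rates, w, threshold, merge_gap_s):
    """Independent oracle: explicit scan + pairwise merging."""
    runs = []
    in_run = False
    for k, r in enumerate(rates):
        if r > threshold and not in_run:
            runs.append([k, k + 1])
            in_run = True
        elif r > threshold:
            runs[-1][1] = k + 1
        else:
            in_run = False
    merged = []
    for a, b in runs:
        if merged and a * w - merged[-1][1] * w <= merge_gap_s + 1e-12:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a * w, b * w) for a, b in merged]


class TestBurstDetection:
    def test_constant_subthreshold_series_has_no_events(self):
        cat = detect_bursts(rates_of(np.full(1000, 10.0)))
        assert cat.merged_events == []

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        data=st.data(),
        n=st.integers(1, 1000),
        threshold=st.floats(1.0, 80.0),
        gap_bins=st.integers(0, 10),
    )
    def test_detector_matches_brute_force_oracle(self, data, n, threshold, gap_bins):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        rates = rng.uniform(0, 100, n).round(0)
        w, merge_gap = 0.1, gap_bins * 0.1
        cat = detect_bursts(rates_of(rates), threshold_hz=threshold, merge_gap_s=merge_gap)
        got = np.asarray(
            [(ev.start_s, ev.end_s) for ev in cat.merged_events], float
        ).reshape(-1, 2)
        expected = np.asarray(
            brute_force_events(rates, w, threshold, merge_gap), float
        ).reshape(-1, 2)
        np.testing.assert_allclose(got, expected)
        for ev in cat.merged_events:
            sl = slice(int(round(ev.start_s / w)), int(round(ev.end_s / w)))
            assert np.max(rates[sl]) > threshold  # every event holds a supra bin
            assert ev.peak_rate_hz == np.max(rates[sl])

    def test_scheduled_bursts_recovered_with_correct_spacing(self):
        cfg = GenConfig(
            preset="gaba_deficient", n_electrodes=2,
            duration_h=600 / 3600, burst_interval_s=(120.0, 120.0), seed=1,
        )
        sch = gen_burst_schedule(cfg)
        cat = detect_bursts(bin_spikes(gen_spike_trains(cfg, sch), 0.1))
        assert len(cat.merged_events) == 5
        np.testing.assert_allclose(np.diff(cat.merged_starts()), 120.0, atol=0.2)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            detect_bursts(rates_of(np.zeros(10)), threshold_hz=0.0)


class TestBandDecomposition:
    def test_hand_built_two_band_series(self):
        # minutes at 5 Hz except minute 3 at 50 Hz, overlapping one event
        vals = np.full(10, 5.0)
        vals[3] = 50.0
        coarse = rates_of(vals, bin_width_s=60.0)
        cat = BurstCatalog(35.0, {"e00": []}, [BurstEvent(190.0, 195.0, 60.0)])
        bands = band_decomposition(coarse, cat)
        row = bands.per_day.iloc[0]
        assert row.mean_burst_band_hz == pytest.approx(50.0)
        assert row.mean_nonburst_band_hz == pytest.approx(5.0)
        assert row.band_gap_hz == pytest.approx(45.0)

    def test_no_bursts_leaves_gap_absent(self):
        coarse = rates_of(np.full(10, 5.0), bin_width_s=60.0)
        cat = BurstCatalog(35.0, {"e00": []}, [])
        row = band_decomposition(coarse, cat).per_day.iloc[0]
        assert np.isnan(row.band_gap_hz) and np.isnan(row.mean_burst_band_hz)

    def test_band_gap_stable_across_days_for_stationary_bursting(self):
        cfg = GenConfig(preset="gaba_deficient", n_electrodes=2, duration_h=72.0, seed=2)
        trains = gen_spike_trains(cfg)
        cat = detect_bursts(bin_spikes(trains, 0.1))
        bands = band_decomposition(bin_spikes(trains, 60.0), cat)
        gaps = bands.per_day.band_gap_hz.to_numpy()
        assert np.all(np.isfinite(gaps))
        assert np.ptp(gaps) / np.mean(gaps) < 0.15


class TestSynchrony:
    def test_duplicated_series_fully_correlated(self):
        r = np.random.default_rng(0).uniform(0, 30, 600)
        rs = RateSeriesSet(0.1, {"a": r.copy(), "b": r.copy(), "c": r.copy()})
        corr = synchrony_matrix(rs)
        np.testing.assert_allclose(corr.matrix, 1.0)
        assert corr.mean_offdiag == pytest.approx(1.0)

    def test_zero_variance_series_excluded_from_mean(self):
        rng = np.random.default_rng(1)
        rs = RateSeriesSet(
            0.1, {"a": rng.uniform(0, 5, 100), "b": rng.uniform(0, 5, 100), "c": np.zeros(100)}
        )
        corr = synchrony_matrix(rs)
        assert np.isnan(corr.matrix[0, 2])
        assert np.isfinite(corr.mean_offdiag)

    def test_independent_trains_uncorrelated(self):
        means = []
        for seed in range(20):
            cfg = GenConfig(preset="wt", n_electrodes=4, duration_h=0.25, seed=seed)
            fine = bin_spikes(gen_spike_trains(cfg), 0.1)
            means.append(synchrony_matrix(fine).mean_offdiag)
        n_bins = 9000
        assert abs(np.mean(means)) < 3 / np.sqrt(n_bins)

    def test_gaba_deficient_more_synchronous_than_wt(self):
        wins = 0
        n_pairs = 40
        for seed in range(n_pairs):
            ko = GenConfig(
                preset="gaba_deficient", n_electrodes=6, duration_h=0.25, seed=seed
            )
            wt = GenConfig(preset="wt", n_electrodes=6, duration_h=0.25, seed=seed)
            m_ko = synchrony_matrix(bin_spikes(gen_spike_trains(ko), 0.1)).mean_offdiag
            m_wt = synchrony_matrix(bin_spikes(gen_spike_trains(wt), 0.1)).mean_offdiag
            wins += m_ko > m_wt
        assert wins >= 0.95 * n_pairs

    def test_single_electrode_rejected(self):
        with pytest.raises(ConfigurationError):
            synchrony_matrix(rates_of(np.zeros(10)))


class TestSupraFractionMonotonicity:
    def test_fraction_monotone_in_burst_duration_and_interval(self):
        def frac(duration_s, interval_s):
            cfg = GenConfig(
                preset="gaba_deficient", n_electrodes=1, duration_h=1.0,
                burst_duration_s=duration_s, burst_interval_s=(interval_s, interval_s),
                seed=3,
            )
            fine = bin_spikes(gen_spike_trains(cfg), 0.1)
            return bin_ratio_distribution(fine).frac_above_35hz_pct

        by_duration = [frac(d, 150.0) for d in (2.0, 5.0, 8.0)]
        assert np.all(np.diff(by_duration) >= 0)
        by_interval = [frac(5.0, i) for i in (120.0, 150.0, 180.0)]
        assert np.all(np.diff(by_interval) <= 0)


class TestPhaseProfile:
    def anchor(self, cfg):
        return CTAnchor(cfg.per2_peak_s, cfg.circadian_period_h)

    def test_uniform_bursting_gives_flat_profile(self):
        cfg = GenConfig(preset="gaba_deficient", n_electrodes=2, duration_h=48.0, seed=5)
        fine = bin_spikes(gen_spike_trains(cfg), 0.1)
        cat = detect_bursts(fine)
        prof = burst_phase_profile(cat, fine, self.anchor(cfg))
        rel = prof.rel_burst_count[np.isfinite(prof.rel_burst_count)]
        assert np.all(np.abs(rel - 1.0) < 0.35)
        assert np.nanmean(prof.rel_burst_count) == pytest.approx(1.0, abs=1e-9)

    def test_bursts_confined_to_one_window_profile(self):
        # all supra bins inside the CT8 window of each cycle
        cfg = GenConfig(duration_h=48.0)
        tau_s = cfg.period_s
        n = int(48 * 36000)
        vals = np.zeros(n)
        t = np.arange(n) * 0.1
        for k in range(3):
            c = cfg.per2_peak_s + (8.0 - 12.0) / 24.0 * tau_s + k * tau_s
            vals[(t >= c - 300) & (t < c + 300)] = 60.0
        rs = rates_of(vals)
        cat = detect_bursts(rs)
        prof = burst_phase_profile(cat, rs, self.anchor(cfg))
        rel = prof.rel_burst_count
        j8 = int(np.flatnonzero(prof.window_centers_ct == 8.0)[0])
        observed = np.isfinite(rel)
        assert rel[j8] == pytest.approx(observed.sum(), rel=1e-6)
        others = rel[observed & (prof.window_centers_ct != 8.0)]
        np.testing.assert_allclose(others, 0.0)

    def test_profile_invariant_under_doubling_all_rates(self):
        cfg = GenConfig(duration_h=48.0)
        rng = np.random.default_rng(7)
        vals = np.where(rng.random(48 * 36000) < 0.01, 60.0, 1.0)
        rs1, rs2 = rates_of(vals), rates_of(2 * vals)
        p1 = burst_phase_profile(detect_bursts(rs1), rs1, self.anchor(cfg))
        p2 = burst_phase_profile(detect_bursts(rs2), rs2, self.anchor(cfg))
        np.testing.assert_allclose(p1.rel_burst_count, p2.rel_burst_count)
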