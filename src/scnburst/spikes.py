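"""Burst-firing statistics on multi-electrode spike trains.

The operational burst definition is a multiunit firing rate above 35 Hz in a
100-ms bin; events last a few seconds and, in GABA-deficient tissue, recur
every 2-3 min in synchrony across the whole slice.  This module implements
the bin-ratio distribution around that criterion, run-length burst
detection, the two-band (burst / non-burst) decomposition of 1-min rate
series, pairwise synchrony matrices, and the circadian phase profile of
burst occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import (
    BurstCatalog,
    BurstEvent,
    ConfigurationError,
    RateSeriesSet,
    SpikeTrainSet,
)
from .rhythms import CTAnchor

__all__ = [
    "bin_spikes",
    "BinRatioDistribution",
    "bin_ratio_distribution",
    "BurstDetector",
    "detect_bursts",
    "BandSummary",
    "band_decomposition",
    "CorrelationMatrix",
    "synchrony_matrix",
    "PhaseProfile",
    "burst_phase_profile",
]

BURST_THRESHOLD_HZ = 35.0


def bin_spikes(trains: SpikeTrainSet, bin_width_s: float) -> RateSeriesSet:
    """Bin spike counts into firing rates (Hz).

    Bins are left-closed/right-open ``[k*w, (k+1)*w)`` from time 0; a partial
    trailing bin is dropped so counts are deterministic.
    """
    if bin_width_s <= 0:
        raise ConfigurationError("bin_width_s must be positive")
    n_bins = int(np.floor(trains.duration_s / bin_width_s + 1e-9))
    if n_bins < 1:
        raise ConfigurationError("record shorter than one bin")
    rates = {}
    for eid in trains.electrodes:
        t = trains.spikes[eid]
        # epsilon keeps spikes intended exactly on a bin edge in the later
        # (left-closed) bin despite floating-point representation
        idx = np.floor(t / bin_width_s + 1e-6).astype(np.int64)
        idx = idx[idx < n_bins]
        counts = np.bincount(idx, minlength=n_bins)
        rates[eid] = counts / bin_width_s
    return RateSeriesSet(
        bin_width_s=bin_width_s, rates=rates, t_start_s=0.0, scn_mask=trains.scn_mask
    )


@dataclass
class BinRatioDistribution:
    """Relative abundance of 100-ms bin rates, as % of the total bin count."""

    freq_edges_hz: np.ndarray
    bin_fraction_pct: np.ndarray
    n_bins_total: int
    frac_above_35hz_pct: float


def bin_ratio_distribution(
    rates: RateSeriesSet,
    window_s: tuple[float, float] | None = None,
    freq_edges_hz: np.ndarray | None = None,
    threshold_hz: float = BURST_THRESHOLD_HZ,
) -> BinRatioDistribution:
    """Histogram of bin rates pooled over SCN electrodes, in % of total bins.

    ``n_bins_total`` counts the bins of a single electrode in the window
    (6000 for a 10-min record in 100-ms bins); the histogram pools all SCN
    electrodes, and ``frac_above_35hz_pct`` is the percentage of pooled bins
    strictly above the burst criterion.
    """
    if freq_edges_hz is None:
        freq_edges_hz = np.arange(0.0, 105.0, 5.0)
    freq_edges_hz = np.asarray(freq_edges_hz, dtype=float)
    sl = (
        rates.window_indices(*window_s)
        if window_s is not None
        else slice(0, rates.n_bins)
    )
    pooled = np.concatenate([rates.rates[e][sl] for e in rates.scn_electrodes])
    if pooled.size == 0:
        raise ConfigurationError("window shorter than one bin")
    edges = np.concatenate([freq_edges_hz, [np.inf]])
    hist, _ = np.histogram(pooled, bins=edges)
    return BinRatioDistribution(
        freq_edges_hz=freq_edges_hz,
        bin_fraction_pct=100.0 * hist / pooled.size,
        n_bins_total=sl.stop - sl.start,
        frac_above_35hz_pct=100.0 * float(np.mean(pooled > threshold_hz)),
    )


def _runs_above(x: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs (start, stop) of samples strictly above threshold."""
    above = x > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        stops = np.concatenate([stops, [len(x)]])
    return list(zip(starts.tolist(), stops.tolist()))


def _merge_intervals(
    intervals: list[tuple[float, float, float]], gap_s: float
) -> list[BurstEvent]:
    """Fuse sorted (start, end, peak) intervals separated by <= gap_s."""
    merged: list[list[float]] = []
    for s, e, p in sorted(intervals):
        if merged and s - merged[-1][1] <= gap_s + 1e-9:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = max(merged[-1][2], p)
        else:
            merged.append([s, e, p])
    return [BurstEvent(s, e, p) for s, e, p in merged]


class BurstDetector(BaseEstimator):
    """Run-length burst detector on 100-ms binned rate series.

    A burst event is a maximal run of bins strictly above ``threshold_hz``;
    runs separated by at most ``merge_gap_s`` are fused into one event
    (sub-second dips inside a seconds-long burst belong to the same event).

    Attributes (after :meth:`fit`)
    ------------------------------
    events_ : dict
        Per-electrode event lists.
    merged_events_ : list
        Slice-level union of events over SCN electrodes.
    catalog_ : BurstCatalog
    """

    def __init__(self, threshold_hz: float = BURST_THRESHOLD_HZ, merge_gap_s: float = 0.5):
        self.threshold_hz = threshold_hz
        self.merge_gap_s = merge_gap_s

    def fit(self, X: RateSeriesSet, y=None) -> "BurstDetector":
        if self.threshold_hz <= 0:
            raise ConfigurationError("threshold_hz must be positive")
        w = X.bin_width_s
        events: dict[str, list[BurstEvent]] = {}
        slice_intervals: list[tuple[float, float, float]] = []
        for eid in X.electrodes:
            r = X.rates[eid]
            ivs = [
                (
                    X.t_start_s + a * w,
                    X.t_start_s + b * w,
                    float(np.max(r[a:b])),
                )
                for a, b in _runs_above(r, self.threshold_hz)
            ]
            events[eid] = _merge_intervals(ivs, self.merge_gap_s)
            if X.scn_mask is None or eid in X.scn_mask:
                slice_intervals.extend(
                    (ev.start_s, ev.end_s, ev.peak_rate_hz) for ev in events[eid]
                )
        self.events_ = events
        self.merged_events_ = _merge_intervals(slice_intervals, self.merge_gap_s)
        self.catalog_ = BurstCatalog(
            threshold_hz=self.threshold_hz,
            events=events,
            merged_events=self.merged_events_,
        )
        return self


def detect_bursts(
    rates: RateSeriesSet,
    threshold_hz: float = BURST_THRESHOLD_HZ,
    merge_gap_s: float = 0.5,
) -> BurstCatalog:
    """Detect burst events; see :class:`BurstDetector`."""
    return BurstDetector(threshold_hz, merge_gap_s).fit(rates).catalog_


@dataclass
class BandSummary:
    """Per-day means of the burst-containing and burst-free 1-min rate bands.

    ``per_day`` has one row per 24-h segment with columns ``day``,
    ``mean_burst_band_hz``, ``mean_nonburst_band_hz``, ``band_gap_hz`` and
    the minute counts per band; a day with no burst-containing minutes has
    NaN (absent) in the burst band and gap columns.
    """

    per_day: pd.DataFrame


def band_decomposition(rates_1min: RateSeriesSet, catalog: BurstCatalog) -> BandSummary:
    """Split the 1-min electrode-mean rate series into burst / non-burst bands.

    A minute is burst-containing iff it overlaps any slice-level merged burst
    event; band means and their difference are computed per 24-h day.
    """
    w = rates_1min.bin_width_s
    mean_rate = rates_1min.mean_rate()
    edges = rates_1min.bin_times()
    burst_min = np.zeros(rates_1min.n_bins, dtype=bool)
    for ev in catalog.merged_events:
        k0 = int(np.floor((ev.start_s - rates_1min.t_start_s) / w))
        k1 = int(np.ceil((ev.end_s - rates_1min.t_start_s) / w))
        burst_min[max(k0, 0) : min(k1, len(burst_min))] = True
    day_idx = np.floor(edges / 86400.0).astype(int)
    rows = []
    for day in np.unique(day_idx):
        m = day_idx == day
        b = burst_min & m
        nb = ~burst_min & m
        mean_b = float(np.mean(mean_rate[b])) if b.any() else np.nan
        mean_nb = float(np.mean(mean_rate[nb])) if nb.any() else np.nan
        rows.append(
            {
                "day": int(day),
                "mean_burst_band_hz": mean_b,
                "mean_nonburst_band_hz": mean_nb,
                "band_gap_hz": mean_b - mean_nb if b.any() and nb.any() else np.nan,
                "n_burst_min": int(b.sum()),
                "n_nonburst_min": int(nb.sum()),
            }
        )
    return BandSummary(per_day=pd.DataFrame(rows))


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations of electrode rate series."""

    electrodes: list[str]
    matrix: np.ndarray
    mean_offdiag: float


def synchrony_matrix(
    rates: RateSeriesSet, window_s: tuple[float, float] | None = None
) -> CorrelationMatrix:
    """Pearson correlation of 100-ms rate series for all SCN electrode pairs.

    Zero-variance series give undefined (NaN) correlations, excluded from
    ``mean_offdiag``; the diagonal is 1 by definition.
    """
    ids = rates.scn_electrodes
    if len(ids) < 2:
        raise ConfigurationError("synchrony needs at least two SCN electrodes")
    sl = (
        rates.window_indices(*window_s)
        if window_s is not None
        else slice(0, rates.n_bins)
    )
    X = np.stack([rates.rates[e][sl] for e in ids])
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    C[sd == 0, :] = np.nan
    C[:, sd == 0] = np.nan
    np.fill_diagonal(C, 1.0)
    off = C[~np.eye(len(ids), dtype=bool)]
    mean_off = float(np.nanmean(off)) if np.any(np.isfinite(off)) else np.nan
    return CorrelationMatrix(electrodes=ids, matrix=C, mean_offdiag=mean_off)


@dataclass
class PhaseProfile:
    """Burst-bin counts in 10-min windows every 4 CT hours, relative to the
    daily mean; an entry of NaN marks a window never fully observed."""

    window_centers_ct: np.ndarray
    rel_burst_count: np.ndarray
    mean_counts: np.ndarray
    daily_mean: float


def burst_phase_profile(
    catalog: BurstCatalog,
    rates: RateSeriesSet,
    ct_anchor: CTAnchor,
    window_min: float = 10.0,
    step_ct_h: float = 4.0,
) -> PhaseProfile:
    """Circadian phase dependence of burst occurrence.

    Counts supra-threshold 100-ms bins of the SCN electrode-mean rate in
    10-min windows centered every 4 CT hours, expresses each cycle's counts
    relative to that cycle's mean, and averages across cycles.  A flat
    profile near 1 indicates phase-independent bursting.
    """
    tau_s = ct_anchor.tau_h * 3600.0
    mean_rate = rates.mean_rate()
    supra = mean_rate > catalog.threshold_hz
    t0 = rates.t_start_s
    t_end = t0 + rates.n_bins * rates.bin_width_s
    centers_ct = np.arange(0.0, 24.0, step_ct_h)
    half = window_min * 30.0  # half-window in seconds
    # time of CT=c in cycle k: anchor + (c - 12)/24*tau + k*tau
    k_min = int(np.floor((t0 - ct_anchor.per2_peak_s) / tau_s)) - 1
    k_max = int(np.ceil((t_end - ct_anchor.per2_peak_s) / tau_s)) + 1
    counts_per_cycle: list[np.ndarray] = []
    for k in range(k_min, k_max + 1):
        row = np.full(len(centers_ct), np.nan)
        for j, c in enumerate(centers_ct):
            center = ct_anchor.per2_peak_s + (c - 12.0) / 24.0 * tau_s + k * tau_s
            if center - half < t0 or center + half > t_end:
                continue
            sl = rates.window_indices(center - half, center + half)
            row[j] = float(np.sum(supra[sl]))
        if np.any(np.isfinite(row)):
            counts_per_cycle.append(row)
    if not counts_per_cycle:
        raise ConfigurationError("recording does not cover any full profile window")
    counts = np.array(counts_per_cycle)
    mean_counts = np.nanmean(counts, axis=0)
    daily_mean = float(np.nanmean(mean_counts))
    if daily_mean > 0:
        rel = np.where(np.isfinite(mean_counts), mean_counts / daily_mean, np.nan)
    else:  # no bursts anywhere: profile of zeros, flagged by daily_mean == 0
        rel = np.where(np.isfinite(mean_counts), 0.0, np.nan)
    return PhaseProfile(
        window_centers_ct=centers_ct,
        rel_burst_count=rel,
        mean_counts=mean_counts,
        daily_mean=daily_mean,
    )
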