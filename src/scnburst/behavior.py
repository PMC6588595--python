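"""Actogram analytics: onsets, variability, daily profiles, periodogram.

Activity onsets are located with a 6 h / 6 h contrast template (mean
activity in the following window minus the preceding window), a declared
stand-in for unpublished commercial onset detectors; regression of onsets on
cycle number gives the free-running period and the cycle-to-cycle
variability (residual SD, minutes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import Actogram, ConfigurationError
from .rhythms import PeriodogramResult, chisq_periodogram

__all__ = [
    "OnsetSeries",
    "OnsetDetector",
    "detect_onsets",
    "daily_profile",
    "activity_partition",
    "behavior_period",
]


@dataclass
class OnsetSeries:
    cycle_index: np.ndarray
    onsets_h: np.ndarray
    period_h: float
    intercept_h: float
    residual_sd_min: float


class OnsetDetector(BaseEstimator):
    """Template-contrast activity-onset detector.

    For each cycle the onset is the earliest minute maximizing
    ``mean(activity in following template_h) - mean(activity in preceding
    template_h)`` within ``search_h`` of the expected onset (previous onset
    plus ``period_guess_h``).  Cycles with no activity near the expected
    onset are skipped.  A least-squares line through onset time vs cycle
    number estimates the period (slope) and the cycle-to-cycle variability
    (residual SD, minutes).
    """

    def __init__(
        self,
        period_guess_h: float = 24.0,
        template_h: float = 6.0,
        search_h: float = 6.0,
        min_cycles: int = 7,
    ):
        self.period_guess_h = period_guess_h
        self.template_h = template_h
        self.search_h = search_h
        self.min_cycles = min_cycles

    def fit(self, act: Actogram, y=None) -> "OnsetDetector":
        c = np.asarray(act.counts, dtype=float)
        dt_min = act.bin_width_s / 60.0
        if dt_min != 1.0:
            raise ConfigurationError("onset detection expects 1-min bins")
        n = c.size
        period_min = self.period_guess_h * 60.0
        n_cycles = int(np.floor(n / period_min))
        if n_cycles < self.min_cycles:
            raise ConfigurationError(f"need >= {self.min_cycles} cycles of data")
        tw = int(round(self.template_h * 60.0))
        sw = int(round(self.search_h * 60.0))
        s = np.concatenate([[0.0], np.cumsum(c)])
        # contrast(i) = mean c[i:i+tw] - mean c[i-tw:i], valid for tw <= i <= n-tw
        idx = np.arange(tw, n - tw + 1)
        contrast = (s[idx + tw] - s[idx]) / tw - (s[idx] - s[idx - tw]) / tw
        cyc, onsets = [], []
        expected = None
        for k in range(n_cycles):
            center = expected + period_min if expected is not None else 12.0 * 60.0 + k * period_min
            lo = int(max(np.ceil(center - sw), tw))
            hi = int(min(np.floor(center + sw), n - tw))
            if hi <= lo:
                continue
            seg = contrast[lo - tw : hi - tw + 1]
            if not np.any(c[lo : hi + tw]):  # no activity in this cycle's window
                expected = center
                continue
            best = lo + int(np.argmax(seg))
            cyc.append(k)
            onsets.append(best)
            expected = float(best)
        if len(onsets) < 3:
            raise ConfigurationError("too few detectable onsets")
        cyc_a = np.asarray(cyc, dtype=float)
        on_h = np.asarray(onsets, dtype=float) / 60.0
        slope, intercept = np.polyfit(cyc_a, on_h, 1)
        resid_min = (on_h - (slope * cyc_a + intercept)) * 60.0
        dof = max(len(onsets) - 2, 1)
        sd = float(np.sqrt(np.sum(resid_min**2) / dof))
        self.cycle_index_ = cyc_a.astype(int)
        self.onsets_h_ = on_h
        self.period_h_ = float(slope)
        self.intercept_h_ = float(intercept)
        self.residual_sd_min_ = sd
        return self

    def result_(self) -> OnsetSeries:
        return OnsetSeries(
            cycle_index=self.cycle_index_,
            onsets_h=self.onsets_h_,
            period_h=self.period_h_,
            intercept_h=self.intercept_h_,
            residual_sd_min=self.residual_sd_min_,
        )


def detect_onsets(
    act: Actogram,
    period_guess_h: float = 24.0,
    template_h: float = 6.0,
    search_h: float = 6.0,
) -> OnsetSeries:
    """Detect activity onsets; see :class:`OnsetDetector`."""
    det = OnsetDetector(period_guess_h, template_h, search_h)
    return det.fit(act).result_()


def daily_profile(
    act: Actogram, fold_period_h: float = 24.0, bin_h: float = 2.0
) -> pd.DataFrame:
    """Mean activity per ``bin_h``-hour bin of the folded cycle.

    Counts are folded at ``fold_period_h`` and averaged (mean count per
    1-min bin) within each 2-h class.
    """
    if fold_period_h < bin_h:
        raise ConfigurationError("fold period must be at least one profile bin")
    t_h = (act.t0_s / 3600.0 + np.arange(act.n_bins) * act.bin_width_s / 3600.0)
    phase = t_h % fold_period_h
    k = np.floor(phase / bin_h).astype(int)
    n_classes = int(np.ceil(fold_period_h / bin_h))
    counts = np.asarray(act.counts, dtype=float)
    mean = np.full(n_classes, np.nan)
    for j in range(n_classes):
        m = k == j
        if m.any():
            mean[j] = counts[m].mean()
    return pd.DataFrame(
        {"bin_start_h": np.arange(n_classes) * bin_h, "mean_activity": mean}
    )


def activity_partition(
    act: Actogram, onsets: OnsetSeries | None = None
) -> pd.DataFrame:
    """Summed activity per light vs dark (or subjective day vs night) cycle.

    Under LD the recorded light schedule partitions each 24-h day.  Under DD
    the subjective night is the 12 h following each detected onset (onset :=
    CT12 for behavior) and the subjective day is the remainder of the cycle.
    Returns one row per cycle with ``light_sum``/``dark_sum`` (or
    ``day_sum``/``night_sum``) and their difference.
    """
    counts = np.asarray(act.counts, dtype=float)
    if not act.is_dd:
        if act.light is None:
            raise ConfigurationError("LD partition requires a light schedule")
        n_days = act.n_bins // (24 * 60)
        rows = []
        for d in range(n_days):
            sl = slice(d * 24 * 60, (d + 1) * 24 * 60)
            c, lt = counts[sl], act.light[sl]
            light = float(c[lt == "L"].sum())
            dark = float(c[lt == "D"].sum())
            rows.append(
                {"cycle": d, "light_sum": light, "dark_sum": dark, "diff": dark - light}
            )
        return pd.DataFrame(rows)
    if onsets is None:
        onsets = detect_onsets(act)
    rows = []
    on_min = onsets.onsets_h * 60.0
    period_min = onsets.period_h * 60.0
    for i, (k, on) in enumerate(zip(onsets.cycle_index, on_min)):
        night = slice(int(round(on)), min(int(round(on + 12 * 60)), act.n_bins))
        day_end = on_min[i + 1] if i + 1 < len(on_min) else on + period_min
        day = slice(int(round(on + 12 * 60)), min(int(round(day_end)), act.n_bins))
        night_sum = float(counts[night].sum())
        day_sum = float(counts[day].sum())
        rows.append(
            {
                "cycle": int(k),
                "night_sum": night_sum,
                "day_sum": day_sum,
                "diff": night_sum - day_sum,
            }
        )
    return pd.DataFrame(rows)


def behavior_period(
    act: Actogram,
    days: int = 28,
    period_range_h: tuple[float, float] = (20.0, 28.0),
    alpha: float = 0.01,
) -> PeriodogramResult:
    """Chi-square periodogram of 1-min activity counts over ``days`` of DD."""
    counts = np.asarray(act.counts, dtype=float)
    need = days * 24 * 60
    if act.light is not None:
        dd = act.light == "D"
        if act.is_dd:
            seg = counts
        else:
            # use the trailing all-dark span
            run_end = act.n_bins
            run_start = run_end
            while run_start > 0 and dd[run_start - 1]:
                run_start -= 1
            seg = counts[run_start:run_end]
    else:
        seg = counts
    if seg.size < need:
        raise ConfigurationError(f"need >= {days} days of DD data")
    seg = seg[-need:]
    return chisq_periodogram(seg, act.bin_width_s, period_range_h, alpha)
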