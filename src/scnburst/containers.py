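"""Core data containers shared across the analysis stages.

All timestamps are seconds from recording start; circadian phase is expressed
in hours or in circadian time (CT), where CT12 is anchored to the PER2 peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "StageError",
    "SpikeTrainSet",
    "RateSeriesSet",
    "ImageStack",
    "BurstEvent",
    "BurstCatalog",
    "Actogram",
    "CalciumTraceSet",
]


class ConfigurationError(ValueError):
    """Invalid configuration or parameter value."""


class StageError(RuntimeError):
    """A pipeline stage failed on otherwise valid configuration."""


@dataclass
class SpikeTrainSet:
    """Per-electrode spike timestamps for one slice recording.

    Parameters
    ----------
    electrodes:
        Electrode identifiers, in display order.
    spikes:
        Mapping electrode id -> strictly sorted spike times in seconds,
        all within ``[0, duration_s]``.
    duration_s:
        Total recording length in seconds.
    scn_mask:
        Electrodes judged to lie on the SCN; slice-level statistics are
        restricted to these.  ``None`` means all electrodes.
    """

    electrodes: list[str]
    spikes: dict[str, np.ndarray]
    duration_s: float
    scn_mask: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.electrodes:
            raise ConfigurationError("SpikeTrainSet requires at least one electrode")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        for eid in self.electrodes:
            t = np.asarray(self.spikes.get(eid, np.empty(0)), dtype=float)
            self.spikes[eid] = t
            if t.size:
                if t[0] < 0 or t[-1] > self.duration_s:
                    raise ConfigurationError(
                        f"spike times of electrode {eid!r} outside [0, duration]"
                    )
                if np.any(np.diff(t) <= 0):
                    raise ConfigurationError(
                        f"spike times of electrode {eid!r} not strictly sorted"
                    )
        if self.scn_mask is not None:
            self.scn_mask = frozenset(self.scn_mask)
            unknown = self.scn_mask - set(self.electrodes)
            if unknown:
                raise ConfigurationError(f"scn_mask references unknown electrodes {unknown}")

    @property
    def scn_electrodes(self) -> list[str]:
        if self.scn_mask is None:
            return list(self.electrodes)
        return [e for e in self.electrodes if e in self.scn_mask]


@dataclass
class RateSeriesSet:
    """Binned firing-rate series per electrode.

    ``rates[e][k]`` is the firing rate (Hz) in the left-closed bin
    ``[t_start_s + k*w, t_start_s + (k+1)*w)``.
    """

    bin_width_s: float
    rates: dict[str, np.ndarray]
    t_start_s: float = 0.0
    scn_mask: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.bin_width_s <= 0:
            raise ConfigurationError("bin_width_s must be positive")
        lengths = {len(v) for v in self.rates.values()}
        if len(lengths) > 1:
            raise ConfigurationError("rate series must have equal length across electrodes")
        for eid, r in self.rates.items():
            r = np.asarray(r, dtype=float)
            if np.any(r < 0):
                raise ConfigurationError("rates must be non-negative")
            self.rates[eid] = r

    @property
    def electrodes(self) -> list[str]:
        return list(self.rates)

    @property
    def scn_electrodes(self) -> list[str]:
        if self.scn_mask is None:
            return self.electrodes
        return [e for e in self.rates if e in self.scn_mask]

    @property
    def n_bins(self) -> int:
        return len(next(iter(self.rates.values())))

    def bin_times(self) -> np.ndarray:
        """Left edges of the bins, seconds."""
        return self.t_start_s + np.arange(self.n_bins) * self.bin_width_s

    def window_indices(self, t0_s: float, t1_s: float) -> slice:
        """Slice of bins fully contained in ``[t0_s, t1_s)``."""
        k0 = int(np.ceil((t0_s - self.t_start_s) / self.bin_width_s - 1e-9))
        k1 = int(np.floor((t1_s - self.t_start_s) / self.bin_width_s + 1e-9))
        k0 = max(k0, 0)
        k1 = min(k1, self.n_bins)
        if k1 <= k0:
            raise ConfigurationError("window shorter than one bin")
        return slice(k0, k1)

    def mean_rate(self, electrodes: Sequence[str] | None = None) -> np.ndarray:
        """Electrode-mean rate series (Hz per bin)."""
        ids = list(electrodes) if electrodes is not None else self.scn_electrodes
        if not ids:
            raise ConfigurationError("no electrodes selected")
        return np.mean([self.rates[e] for e in ids], axis=0)


@dataclass
class ImageStack:
    """Time-ordered raster frames of bioluminescence or fluorescence.

    ``frames`` has shape (T, H, W); row 0 is dorsal by convention.
    """

    frames: np.ndarray
    frame_interval_s: float
    pixel_size_um: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ConfigurationError("frames must be a (T>=2, H, W) array")
        if self.frame_interval_s <= 0:
            raise ConfigurationError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frame_times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_frames) * self.frame_interval_s


@dataclass(frozen=True)
class BurstEvent:
    start_s: float
    end_s: float
    peak_rate_hz: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class BurstCatalog:
    """Detected burst events per electrode plus the slice-level merged union."""

    threshold_hz: float
    events: dict[str, list[BurstEvent]]
    merged_events: list[BurstEvent]

    def merged_starts(self) -> np.ndarray:
        return np.array([ev.start_s for ev in self.merged_events], dtype=float)

    def n_events(self, electrode: str | None = None) -> int:
        if electrode is None:
            return len(self.merged_events)
        return len(self.events[electrode])


@dataclass
class Actogram:
    """Behavioral activity counts in 1-min bins with a light-schedule annotation.

    ``light`` holds one of ``"L"``/``"D"`` per bin; constant darkness is all
    ``"D"``.  ``true_onsets_h`` is populated by the synthetic generator only and
    carries the ground-truth activity onsets for recovery tests.
    """

    counts: np.ndarray
    bin_width_s: float = 60.0
    t0_s: float = 0.0
    light: np.ndarray | None = None
    true_onsets_h: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ConfigurationError("activity counts must be non-negative")
        if self.light is not None:
            self.light = np.asarray(self.light, dtype="U1")
            if len(self.light) != len(self.counts):
                raise ConfigurationError("light schedule must cover all bins")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def duration_h(self) -> float:
        return self.n_bins * self.bin_width_s / 3600.0

    @property
    def is_dd(self) -> bool:
        return self.light is None or bool(np.all(self.light == "D"))


@dataclass
class CalciumTraceSet:
    """Per-ROI calcium traces sampled at a fixed frame interval."""

    frame_interval_s: float
    traces: dict[str, np.ndarray]
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ConfigurationError("frame_interval_s must be positive")
        for k, v in self.traces.items():
            self.traces[k] = np.asarray(v, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.traces.values())))

    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_frames) * self.frame_interval_s
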