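"""Synthetic recordings with the statistical structure of cultured-SCN data.

The generator emulates two preparations:

``wt``
    Multiunit firing whose rate follows a circadian sinusoid between a trough
    of 2 Hz and a peak of 18 Hz (peak at CT8), with an absolute refractory
    period of 35 ms per electrode.  The refractory period caps every 100-ms
    bin at 30 Hz, so wild-type recordings never cross the 35-Hz burst
    criterion.

``gaba_deficient``
    The same circadian baseline plus slice-wide synchronized bursts: regular
    spiking at ``burst_rate_hz`` (35-80 Hz admissible) for a few seconds,
    recurring at 2-3 min intervals, with start times independent of circadian
    phase.  Calcium traces carry a fast-rising, exponentially decaying
    transient co-timed with every burst.

Conventions: generator time 0 is CT0; the firing-rate peak sits at CT8 and
the PER2 peak (the CT12 anchor) at CT12.  All randomness flows from a single
seed through named substreams (one per generated modality), so a fixed seed
gives bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import (
    Actogram,
    CalciumTraceSet,
    ConfigurationError,
    ImageStack,
    SpikeTrainSet,
)

__all__ = [
    "GenConfig",
    "BurstSchedule",
    "gen_burst_schedule",
    "gen_spike_trains",
    "gen_image_stack",
    "gen_calcium_traces",
    "gen_actogram",
]

# Firing peaks at CT8 (phase of highest multiunit activity in the slice);
# the PER2::LUC peak defines CT12.
FIRING_PEAK_CT = 8.0
PER2_PEAK_CT = 12.0

# Substream labels for the documented seed-splitting scheme.
_STREAMS = {
    "schedule": 0,
    "spikes": 1,
    "image": 2,
    "calcium": 3,
    "actogram": 4,
}


@dataclass
class GenConfig:
    """All parameters of the synthetic-recording generator.

    Defaults encode the wild-type/GABA-deficient study conditions: circadian
    firing between 2 and 18 Hz with period 23.86 h, bursts of 60 Hz lasting
    5 s at uniform 2-3 min intervals, hourly PER2 imaging with tight phase
    dispersion, calcium frames every 3 s, and 1-min actogram bins.
    """

    preset: str = "wt"
    n_electrodes: int = 12
    duration_h: float = 24.0
    circadian_period_h: float = 23.86
    peak_rate_hz: float = 18.0
    trough_rate_hz: float = 2.0
    refractory_ms: float = 35.0
    burst_rate_hz: float = 60.0
    burst_duration_s: float = 5.0
    burst_interval_s: tuple[float, float] = (120.0, 180.0)
    # imaging
    img_period_h: float = 23.7
    img_phase_sd_h: float = 0.5
    img_damping_per_cycle: float = 0.9
    img_noise_sd: float = 5.0
    img_mesor: float = 100.0
    img_amplitude: float = 50.0
    img_shape: tuple[int, int] = (32, 32)
    img_frame_interval_h: float = 1.0
    # calcium
    ca_frame_interval_s: float = 3.0
    ca_mesor: float = 100.0
    ca_amplitude: float = 20.0
    ca_noise_sd: float = 2.0
    ca_transient_amp: float = 40.0
    ca_transient_decay_s: float = 15.0
    # behavior
    act_period_h: float = 23.7
    onset_jitter_min: float = 10.0
    act_active_rate: float = 18.0
    act_rest_rate: float = 2.0
    act_light_cycle: str = "DD"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in ("wt", "gaba_deficient"):
            raise ConfigurationError(f"unknown preset {self.preset!r}")
        if self.duration_h <= 0:
            raise ConfigurationError("duration_h must be positive")
        if self.trough_rate_hz > self.peak_rate_hz:
            raise ConfigurationError("trough_rate_hz must not exceed peak_rate_hz")
        if self.trough_rate_hz < 0:
            raise ConfigurationError("rates must be non-negative")
        if self.refractory_ms < 0:
            raise ConfigurationError("refractory_ms must be non-negative")
        if self.peak_rate_hz * self.refractory_ms / 1000.0 >= 1.0:
            raise ConfigurationError(
                "peak_rate_hz * refractory must be < 1 for the dead-time correction"
            )
        if self.preset == "gaba_deficient":
            if not self.burst_rate_hz > 35.0:
                raise ConfigurationError("burst_rate_hz must exceed the 35-Hz criterion")
            lo, hi = self.burst_interval_s
            if not (0 < lo <= hi):
                raise ConfigurationError("burst_interval_s must be an ordered positive range")
            if lo <= self.burst_duration_s:
                raise ConfigurationError(
                    "burst interval lower bound must exceed burst_duration_s"
                )
        if not 0 < self.img_damping_per_cycle <= 1.0:
            raise ConfigurationError("img_damping_per_cycle must be in (0, 1]")
        if self.img_amplitude <= 0 or self.img_period_h <= 0:
            raise ConfigurationError("image amplitude and period must be positive")
        if self.act_light_cycle not in ("DD", "LD"):
            raise ConfigurationError("act_light_cycle must be 'DD' or 'LD'")

    # -- seed splitting -------------------------------------------------
    def rng(self, stream: str, index: int = 0) -> np.random.Generator:
        """Random generator for one named substream.

        Streams are derived from ``(seed, stream id, index)`` via numpy's
        SeedSequence, so modalities and electrodes are independent and the
        whole run is reproducible from the single ``seed``.
        """
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream], index))
        )

    @property
    def duration_s(self) -> float:
        return self.duration_h * 3600.0

    @property
    def period_s(self) -> float:
        return self.circadian_period_h * 3600.0

    @property
    def per2_peak_s(self) -> float:
        """Time of the first PER2 peak (the CT12 anchor)."""
        return PER2_PEAK_CT / 24.0 * self.period_s

    def firing_rate(self, t_s: np.ndarray) -> np.ndarray:
        """Nominal circadian firing rate (Hz) at time ``t_s``."""
        t_peak = FIRING_PEAK_CT / 24.0 * self.period_s
        depth = self.peak_rate_hz - self.trough_rate_hz
        return self.trough_rate_hz + depth * 0.5 * (
            1.0 + np.cos(2.0 * np.pi * (np.asarray(t_s, float) - t_peak) / self.period_s)
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BurstSchedule:
    """Slice-wide burst event times, shared by all electrodes."""

    events: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for (s0, e0), (s1, _e1) in zip(self.events, self.events[1:]):
            if s1 < e0:
                raise ConfigurationError("burst events must be sorted and non-overlapping")

    def __len__(self) -> int:
        return len(self.events)

    def starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.events], dtype=float)

    def ends(self) -> np.ndarray:
        return np.array([e for _, e in self.events], dtype=float)


def gen_burst_schedule(cfg: GenConfig) -> BurstSchedule:
    """Draw the slice-wide burst schedule.

    Start-to-start gaps are i.i.d. uniform on ``cfg.burst_interval_s``; the
    first event starts at t = 0 and the schedule runs to the end of the
    recording.  Start times carry no circadian-phase information.  The ``wt``
    preset has no bursts and yields an empty schedule.
    """
    if cfg.preset == "wt":
        return BurstSchedule([])
    rng = cfg.rng("schedule")
    lo, hi = cfg.burst_interval_s
    events: list[tuple[float, float]] = []
    t = 0.0
    while t < cfg.duration_s:
        events.append((t, min(t + cfg.burst_duration_s, cfg.duration_s)))
        t += rng.uniform(lo, hi) if hi > lo else lo
    return BurstSchedule(events)


def _enforce_refractory(t: np.ndarray, refractory_s: float) -> np.ndarray:
    """Greedy non-paralyzable dead time: keep a spike only if at least
    ``refractory_s`` after the last kept spike."""
    if refractory_s <= 0 or t.size == 0:
        return t
    return _refractory_kernel(np.ascontiguousarray(t, dtype=np.float64), float(refractory_s))


def _refractory_kernel_py(t, r):
    out = np.empty_like(t)
    n = 0
    last = -np.inf
    for x in t:
        if x - last >= r:
            out[n] = x
            n += 1
            last = x
    return out[:n]


try:  # the sequential pass dominates generation time; compile it when possible
    from numba import njit

    _refractory_kernel = njit(cache=False)(_refractory_kernel_py)
except Exception:  # pragma: no cover
    _refractory_kernel = _refractory_kernel_py


def _baseline_spikes(cfg: GenConfig, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous spike train with absolute refractory period.

    A Poisson stream at the dead-time-corrected intensity
    ``lam_p = lam/(1 - lam*r)`` is thinned to the target sinusoid and passed
    through a non-paralyzable dead time ``r``; the realized rate then equals
    the nominal circadian rate while no 100-ms window can hold more than
    ``floor(0.1/r) + 1`` spikes.
    """
    r = cfg.refractory_ms / 1000.0
    lam_max = cfg.peak_rate_hz / (1.0 - cfg.peak_rate_hz * r)
    if lam_max <= 0:
        return np.empty(0)
    n_exp = lam_max * cfg.duration_s
    # homogeneous candidates via exponential gaps (sorted by construction)
    n_draw = int(n_exp + 6.0 * np.sqrt(n_exp) + 16)
    gaps = rng.exponential(1.0 / lam_max, size=n_draw)
    t = np.cumsum(gaps)
    while t.size and t[-1] < cfg.duration_s:  # pragma: no cover - rare top-up
        extra = rng.exponential(1.0 / lam_max, size=max(16, n_draw // 10))
        t = np.concatenate([t, t[-1] + np.cumsum(extra)])
    t = t[t < cfg.duration_s]
    lam_t = cfg.firing_rate(t)
    lam_p = lam_t / (1.0 - lam_t * r)
    keep = rng.random(t.size) < lam_p / lam_max
    return _enforce_refractory(t[keep], r)


def gen_spike_trains(cfg: GenConfig, schedule: BurstSchedule | None = None) -> SpikeTrainSet:
    """Generate per-electrode spike trains for one slice.

    Baseline spiking is an independent refractory renewal process per
    electrode whose instantaneous rate follows the circadian sinusoid.
    During scheduled bursts every electrode fires a regular grid at
    ``cfg.burst_rate_hz`` (identical across electrodes), so each 100-ms bin
    fully inside a burst holds exactly ``burst_rate_hz / 10`` spikes.
    """
    if schedule is None:
        schedule = gen_burst_schedule(cfg)
    starts, ends = schedule.starts(), schedule.ends()
    electrodes = [f"e{i:02d}" for i in range(cfg.n_electrodes)]
    spikes: dict[str, np.ndarray] = {}
    for i, eid in enumerate(electrodes):
        t = _baseline_spikes(cfg, cfg.rng("spikes", i))
        if len(schedule):
            # replace baseline spiking inside bursts with the regular grid
            i0 = np.searchsorted(t, starts, side="left")
            i1 = np.searchsorted(t, ends, side="left")
            delta = np.zeros(t.size + 1, dtype=np.int64)
            np.add.at(delta, i0, 1)
            np.add.at(delta, i1, -1)
            inside = np.cumsum(delta[:-1]) > 0
            t = t[~inside]
            grids = []
            for s, e in schedule.events:
                n_g = int(np.floor((e - s) * cfg.burst_rate_hz * (1 - 1e-12))) + 1
                grids.append(s + np.arange(n_g) / cfg.burst_rate_hz)
            t = np.sort(np.concatenate([t, *grids]))
            t = t[np.concatenate([[True], np.diff(t) > 0])]
        spikes[eid] = np.minimum(t, cfg.duration_s)
    return SpikeTrainSet(
        electrodes=electrodes,
        spikes=spikes,
        duration_s=cfg.duration_s,
        scn_mask=frozenset(electrodes),
    )


def gen_image_stack(cfg: GenConfig) -> ImageStack:
    """Synthetic PER2::LUC image stack.

    Pixel ``i`` emits ``M + A * d**(t/tau) * cos(2*pi*(t - phi_i)/tau)`` plus
    Gaussian noise, with per-pixel acrophase ``phi_i`` wrapped-normal around
    the slice mean (the CT12 anchor) with SD ``img_phase_sd_h``.
    """
    tau_h = cfg.img_period_h
    dt_h = cfg.img_frame_interval_h
    n_frames = int(round(cfg.duration_h / dt_h))
    if n_frames < 2:
        raise ConfigurationError("duration too short for an image stack")
    rng = cfg.rng("image")
    h, w = cfg.img_shape
    t = np.arange(n_frames) * dt_h
    mean_phase_h = PER2_PEAK_CT / 24.0 * tau_h
    phi = rng.normal(mean_phase_h, cfg.img_phase_sd_h, size=(h, w)) % tau_h
    envelope = cfg.img_amplitude * cfg.img_damping_per_cycle ** (t / tau_h)
    frames = cfg.img_mesor + envelope[:, None, None] * np.cos(
        2.0 * np.pi * (t[:, None, None] - phi[None, :, :]) / tau_h
    )
    if cfg.img_noise_sd > 0:
        frames = frames + rng.normal(0.0, cfg.img_noise_sd, size=frames.shape)
    return ImageStack(
        frames=frames,
        frame_interval_s=dt_h * 3600.0,
        pixel_size_um=4.3,
        t0_s=0.0,
    )


def gen_calcium_traces(
    cfg: GenConfig, schedule: BurstSchedule | None = None, n_traces: int | None = None
) -> CalciumTraceSet:
    """Per-ROI calcium traces: circadian baseline plus burst-locked transients.

    Each scheduled burst adds a transient with a one-frame rise and
    exponential decay (``ca_transient_decay_s``); the default amplitude is
    20x the noise SD, comfortably above the 5x floor the detector assumes.
    The circadian calcium baseline peaks in the subjective day (CT6).
    """
    if schedule is None:
        schedule = gen_burst_schedule(cfg)
    if n_traces is None:
        n_traces = cfg.n_electrodes
    dt = cfg.ca_frame_interval_s
    n = int(round(cfg.duration_s / dt))
    if n < 10:
        raise ConfigurationError("duration too short for calcium traces")
    t = np.arange(n) * dt
    ca_peak_s = 6.0 / 24.0 * cfg.period_s
    base = cfg.ca_mesor + cfg.ca_amplitude * np.cos(
        2.0 * np.pi * (t - ca_peak_s) / cfg.period_s
    )
    transient = np.zeros(n)
    for s, _e in schedule.events:
        k0 = int(np.ceil(s / dt - 1e-9))
        if k0 >= n:
            continue
        tt = t[k0:] - s
        transient[k0:] += cfg.ca_transient_amp * np.exp(-tt / cfg.ca_transient_decay_s)
    rng = cfg.rng("calcium")
    traces = {}
    for i in range(n_traces):
        noise = rng.normal(0.0, cfg.ca_noise_sd, size=n) if cfg.ca_noise_sd > 0 else 0.0
        traces[f"roi{i:02d}"] = base + transient + noise
    return CalciumTraceSet(frame_interval_s=dt, traces=traces, t0_s=0.0)


def gen_actogram(cfg: GenConfig) -> Actogram:
    """Synthetic actogram: nocturnal square-wave activity in 1-min bins.

    The animal is active for 12 h per cycle starting at the activity onset;
    under DD onsets free-run at ``act_period_h`` with per-cycle Gaussian
    jitter ``onset_jitter_min``; under LD onsets lock to lights-off (12 h
    into each 24-h day).  Counts are Poisson around the active/rest rates.
    """
    n = int(round(cfg.duration_h * 60))
    t_min = np.arange(n)  # bin start, minutes
    rng = cfg.rng("actogram")
    period_min = (24.0 if cfg.act_light_cycle == "LD" else cfg.act_period_h) * 60.0
    n_cycles = int(np.ceil(cfg.duration_h * 60 / period_min)) + 1
    base_onsets = 12.0 * 60.0 + period_min * np.arange(n_cycles)
    if cfg.act_light_cycle == "DD" and cfg.onset_jitter_min > 0:
        onsets = base_onsets + rng.normal(0.0, cfg.onset_jitter_min, size=n_cycles)
    else:
        onsets = base_onsets.copy()
    rate = np.full(n, float(cfg.act_rest_rate))
    for on in onsets:
        i0, i1 = int(np.ceil(on)), int(np.ceil(on + 12.0 * 60.0))
        rate[max(i0, 0) : min(i1, n)] = cfg.act_active_rate
    counts = rng.poisson(rate)
    if cfg.act_light_cycle == "LD":
        light = np.where((t_min % (24 * 60)) < 12 * 60, "L", "D")
    else:
        light = np.full(n, "D")
    keep = (onsets >= 0) & (onsets < n)
    return Actogram(
        counts=counts,
        bin_width_s=60.0,
        t0_s=0.0,
        light=light,
        true_onsets_h=onsets[keep] / 60.0,
    )
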