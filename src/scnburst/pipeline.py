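"""End-to-end orchestration: generate -> spikes -> rhythms -> imaging -> behavior.

A run is fully described by a :class:`RunConfig`; every defaulted parameter
is echoed into the run manifest together with SHA-256 checksums of all
outputs, so a run can be reproduced exactly from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .containers import ConfigurationError, StageError
from .synth import (
    GenConfig,
    gen_actogram,
    gen_burst_schedule,
    gen_calcium_traces,
    gen_image_stack,
    gen_spike_trains,
)
from . import behavior, imaging, io, rhythms, spikes

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger("scnburst")

ALL_STAGES = ("generate", "spikes", "rhythms", "imaging", "behavior", "report")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "scnburst_run"
    preset: str = "wt"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    gen: dict = field(default_factory=dict)  # GenConfig overrides
    burst_threshold_hz: float = 35.0
    merge_gap_s: float = 0.5
    synchrony_window_min: float = 10.0
    behavior_days: int = 28

    def gen_config(self) -> GenConfig:
        return GenConfig(preset=self.preset, seed=self.seed, **self.gen)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        try:
            cfg = cls(**raw)
            cfg.gen_config()  # validate generator overrides early
        except (TypeError, ConfigurationError) as exc:
            raise ConfigurationError(str(exc)) from exc
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and write outputs plus a manifest.

    Returns the manifest dictionary.  Stage failures raise
    :class:`StageError` tagged with the stage name; configuration problems
    raise :class:`ConfigurationError` before any stage runs.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen_cfg = cfg.gen_config()
    unknown = set(cfg.stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    outputs: dict[str, str] = {}
    report: dict = {"preset": gen_cfg.preset, "seed": gen_cfg.seed}
    ctx: dict = {}

    def _record(name: str, path: Path) -> None:
        outputs[name] = str(path.name)

    for stage in [s for s in ALL_STAGES if s in cfg.stages]:
        log.info("stage %s: start", stage)
        try:
            if stage == "generate":
                _stage_generate(cfg, gen_cfg, outdir, ctx, _record)
            elif stage == "spikes":
                _stage_spikes(cfg, gen_cfg, outdir, ctx, report, _record)
            elif stage == "rhythms":
                _stage_rhythms(cfg, gen_cfg, ctx, report)
            elif stage == "imaging":
                _stage_imaging(cfg, gen_cfg, outdir, ctx, report, _record)
            elif stage == "behavior":
                _stage_behavior(cfg, gen_cfg, ctx, report)
            elif stage == "report":
                p = outdir / "report.json"
                p.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
                _record("report", p)
        except ConfigurationError:
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s: done", stage)

    manifest = {
        "scnburst_version": __version__,
        "config": _jsonable(asdict(cfg)),
        "generator": _jsonable(gen_cfg.to_dict()),
        "outputs": {k: {"file": v, "sha256": _sha256(outdir / v)} for k, v in outputs.items()},
        "report": _jsonable(report),
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest


def _stage_generate(cfg, gen_cfg, outdir, ctx, record) -> None:
    schedule = gen_burst_schedule(gen_cfg)
    trains = gen_spike_trains(gen_cfg, schedule)
    stack = gen_image_stack(gen_cfg)
    ca = gen_calcium_traces(gen_cfg, schedule, n_traces=2)
    act = gen_actogram(gen_cfg)
    ctx.update(schedule=schedule, trains=trains, stack=stack, ca=ca, act=act)
    record("spikes", io.write_spikes(trains, outdir / "spikes.tsv"))
    record("image_stack", io.write_image_stack(stack, outdir / "per2_stack.tif"))
    record("calcium", io.write_calcium(ca, outdir / "calcium.csv"))
    record("actogram", io.write_actogram(act, outdir / "actogram.csv"))


def _ct8_window(gen_cfg, duration_s, width_s=600.0):
    center = 8.0 / 24.0 * gen_cfg.period_s
    if center + width_s / 2 > duration_s:
        return (0.0, min(width_s, duration_s))
    return (center - width_s / 2, center + width_s / 2)


def _stage_spikes(cfg, gen_cfg, outdir, ctx, report, record) -> None:
    trains = ctx["trains"]
    fine = spikes.bin_spikes(trains, 0.1)
    coarse = spikes.bin_spikes(trains, 60.0)
    ctx.update(fine=fine, coarse=coarse)
    win = _ct8_window(gen_cfg, trains.duration_s)
    dist = spikes.bin_ratio_distribution(fine, window_s=win, threshold_hz=cfg.burst_threshold_hz)
    catalog = spikes.detect_bursts(fine, cfg.burst_threshold_hz, cfg.merge_gap_s)
    ctx["catalog"] = catalog
    bands = spikes.band_decomposition(coarse, catalog)
    corr = spikes.synchrony_matrix(fine, window_s=win)
    report["frac_above_35hz_pct"] = dist.frac_above_35hz_pct
    report["n_burst_events"] = len(catalog.merged_events)
    starts = catalog.merged_starts()
    report["median_interburst_s"] = (
        float(np.median(np.diff(starts))) if starts.size > 1 else None
    )
    report["mean_offdiag_correlation"] = corr.mean_offdiag
    bands.per_day.to_csv(outdir / "band_summary.csv", index=False)
    record("band_summary", outdir / "band_summary.csv")
    np.savetxt(outdir / "synchrony_matrix.csv", corr.matrix, delimiter=",", fmt="%.6f")
    record("synchrony_matrix", outdir / "synchrony_matrix.csv")
    if trains.duration_s >= gen_cfg.period_s + 600.0:
        anchor = rhythms.CTAnchor(gen_cfg.per2_peak_s, gen_cfg.circadian_period_h)
        prof = spikes.burst_phase_profile(catalog, fine, anchor)
        report["burst_phase_profile_rel"] = prof.rel_burst_count
    else:
        report["burst_phase_profile_rel"] = None


def _stage_rhythms(cfg, gen_cfg, ctx, report) -> None:
    coarse = ctx.get("coarse")
    if coarse is not None and coarse.n_bins * 60.0 >= 3 * 28 * 3600.0:
        pg = rhythms.chisq_periodogram(coarse.mean_rate(), 60.0)
        report["firing_best_period_h"] = pg.best_period_h
        report["firing_qp_peak"] = pg.qp_peak
    else:
        report["firing_best_period_h"] = None
    stack = ctx["stack"]
    trace = imaging.roi_series(stack, np.ones(stack.shape, dtype=bool))
    t_h = stack.frame_times_s() / 3600.0
    if t_h[-1] - t_h[0] >= gen_cfg.img_period_h:
        fit = rhythms.cosinor_fit(t_h, trace, tau_h=None)
        report["per2_cosinor"] = {
            "mesor": fit.mesor,
            "amplitude": fit.amplitude,
            "acrophase_h": fit.acrophase_h,
            "period_h": fit.period_h,
            "rsq": fit.rsq,
        }
        am = rhythms.amplitude_metrics(t_h, trace, fit.period_h)
        report["per2_damping_ratio"] = am.damping_ratio
    else:
        report["per2_cosinor"] = None


def _stage_imaging(cfg, gen_cfg, outdir, ctx, report, record) -> None:
    stack = ctx["stack"]
    t_span_h = (stack.n_frames - 1) * stack.frame_interval_s / 3600.0
    if t_span_h >= 2 * gen_cfg.img_period_h:
        amap = imaging.pixel_acrophase_map(stack, gen_cfg.img_period_h)
        report["rayleigh_r"] = amap.rayleigh_r()
        np.savetxt(outdir / "acrophase_map.csv", amap.acrophase_h, delimiter=",", fmt="%.4f")
        record("acrophase_map", outdir / "acrophase_map.csv")
    else:
        report["rayleigh_r"] = None
    h, w = stack.shape
    kymo = imaging.line_scan(stack, (0, w // 2), (h - 1, w // 2))
    np.savetxt(outdir / "kymograph.csv", kymo, delimiter=",", fmt="%.4f")
    record("kymograph", outdir / "kymograph.csv")
    ca = ctx["ca"]
    first = next(iter(ca.traces.values()))
    events = imaging.detect_ca_spikes(first, ca.frame_interval_s)
    report["n_ca_events"] = len(events)
    catalog = ctx.get("catalog")
    if catalog is not None:
        # tolerance must cover the calcium sampling interval
        co = imaging.burst_ca_coincidence(
            events, catalog, tol_s=max(2.0, ca.frame_interval_s)
        )
        report["coincidence_ca_near_burst"] = co.frac_ca_near_burst
        report["coincidence_burst_near_ca"] = co.frac_burst_near_ca


def _stage_behavior(cfg, gen_cfg, ctx, report) -> None:
    act = ctx["act"]
    n_cycles = act.duration_h / gen_cfg.act_period_h
    if n_cycles >= 7:
        onsets = behavior.detect_onsets(act, period_guess_h=gen_cfg.act_period_h)
        report["behavior_onset_sd_min"] = onsets.residual_sd_min
        report["behavior_onset_period_h"] = onsets.period_h
    else:
        report["behavior_onset_sd_min"] = None
    if act.duration_h >= cfg.behavior_days * 24:
        pg = behavior.behavior_period(act, days=cfg.behavior_days)
        report["behavior_best_period_h"] = pg.best_period_h
        report["behavior_qp_peak"] = pg.qp_peak
    else:
        report["behavior_best_period_h"] = None
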