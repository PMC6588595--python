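"""Readers and writers for the plain-text and TIFF interchange formats.

Spike trains travel as 2-column tab-separated text (electrode_id, time_s);
image stacks as multi-frame TIFF with a YAML sidecar (frame_interval_s,
pixel_size_um, t0_s); actograms and calcium traces as CSV with header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import Actogram, CalciumTraceSet, ImageStack, SpikeTrainSet

__all__ = [
    "write_spikes",
    "read_spikes",
    "write_image_stack",
    "read_image_stack",
    "write_actogram",
    "read_actogram",
    "write_calcium",
    "read_calcium",
]


def write_spikes(trains: SpikeTrainSet, path: str | Path) -> Path:
    path = Path(path)
    frames = [
        pd.DataFrame({"electrode_id": eid, "time_s": trains.spikes[eid]})
        for eid in trains.electrodes
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
    return path


def read_spikes(
    path: str | Path,
    duration_s: float | None = None,
    scn_mask: frozenset[str] | None = None,
) -> SpikeTrainSet:
    df = pd.read_csv(path, sep="\t", dtype={"electrode_id": str})
    electrodes = sorted(df["electrode_id"].unique())
    spikes = {
        eid: np.sort(df.loc[df["electrode_id"] == eid, "time_s"].to_numpy(float))
        for eid in electrodes
    }
    if duration_s is None:
        duration_s = float(df["time_s"].max()) if len(df) else 1.0
    return SpikeTrainSet(
        electrodes=electrodes,
        spikes=spikes,
        duration_s=duration_s,
        scn_mask=scn_mask,
    )


def write_image_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a multi-frame TIFF plus a ``<stem>.yaml`` metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "frame_interval_s": float(stack.frame_interval_s),
        "pixel_size_um": float(stack.pixel_size_um),
        "t0_s": float(stack.t0_s),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))
    return path


def read_image_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=float)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return ImageStack(
        frames=frames,
        frame_interval_s=meta["frame_interval_s"],
        pixel_size_um=meta["pixel_size_um"],
        t0_s=meta.get("t0_s", 0.0),
    )


def write_actogram(act: Actogram, path: str | Path) -> Path:
    path = Path(path)
    t = act.t0_s + np.arange(act.n_bins) * act.bin_width_s
    light = act.light if act.light is not None else np.full(act.n_bins, "D")
    pd.DataFrame({"time_s": t, "count": act.counts, "light_state": light}).to_csv(
        path, index=False
    )
    return path


def read_actogram(path: str | Path) -> Actogram:
    df = pd.read_csv(path, dtype={"light_state": str})
    t = df["time_s"].to_numpy(float)
    bw = float(np.median(np.diff(t))) if len(t) > 1 else 60.0
    return Actogram(
        counts=df["count"].to_numpy(),
        bin_width_s=bw,
        t0_s=float(t[0]) if len(t) else 0.0,
        light=df["light_state"].to_numpy(dtype="U1"),
    )


def write_calcium(traces: CalciumTraceSet, path: str | Path) -> Path:
    path = Path(path)
    out = {"time_s": traces.times_s()}
    out.update(traces.traces)
    pd.DataFrame(out).to_csv(path, index=False, float_format="%.5f")
    return path


def read_calcium(path: str | Path) -> CalciumTraceSet:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    dt = float(np.median(np.diff(t)))
    traces = {c: df[c].to_numpy(float) for c in df.columns if c != "time_s"}
    return CalciumTraceSet(frame_interval_s=dt, traces=traces, t0_s=float(t[0]))
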