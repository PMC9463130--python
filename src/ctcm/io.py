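"""Readers and writers for videos, masks, traces and results.

Videos travel as multi-page 16-bit TIFF (or 8-bit AVI); masks as PNG;
traces and per-region tables as CSV (comma-separated, '.' decimal, UTF-8,
header row); metrics and ground truth as JSON.  Writers are deterministic:
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .motion import CycleMetrics, MotionTrace, TraceStage
from .synthetic import GroundTruth, VideoClip

__all__ = [
    "write_video",
    "read_video",
    "write_mask",
    "read_mask",
    "write_trace_csv",
    "read_trace_csv",
    "write_metrics_json",
    "write_ground_truth",
    "write_waveform_csv",
]

_U16_MAX = np.iinfo(np.uint16).max


def write_video(clip: VideoClip, path: str | Path) -> Path:
    """Write a clip as multi-page TIFF (16-bit) or AVI (8-bit), by suffix."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = np.round(np.clip(clip.frames, 0, 1) * _U16_MAX).astype(np.uint16)
        tifffile.imwrite(
            path,
            data,
            metadata={"fps": clip.fps, "mm_per_px": clip.mm_per_px},
        )
    elif path.suffix.lower() == ".avi":
        data = np.round(np.clip(clip.frames, 0, 1) * 255).astype(np.uint8)
        iio.imwrite(path, data, fps=clip.fps, codec="rawvideo")
    else:
        raise ValueError(f"unsupported video format: {path.suffix}")
    return path


def read_video(
    path: str | Path, fps: float | None = None, mm_per_px: float | None = None
) -> VideoClip:
    """Read a video into a [0, 1] float stack.

    TIFF metadata written by :func:`write_video` restores fps and pixel
    pitch; otherwise they must be given (fps defaults to 30, the recording
    rate of the rig).
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        fps = fps or float(meta.get("fps", 30.0))
        mm_per_px = mm_per_px or float(meta.get("mm_per_px", 1.0))
        scale = _U16_MAX if data.dtype == np.uint16 else 255
    else:
        data = iio.imread(path)
        if data.ndim == 4:  # RGB video -> luminance
            data = data.mean(axis=-1)
        fps = fps or 30.0
        mm_per_px = mm_per_px or 1.0
        scale = 255
    frames = data.astype(float) / scale
    if frames.ndim == 2:
        frames = frames[None]
    return VideoClip(frames=frames, fps=fps, mm_per_px=mm_per_px)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    data = iio.imread(path)
    if data.ndim == 3:
        data = data[..., 0]
    return data > (data.max() / 2 if data.max() > 0 else 0)


def write_trace_csv(trace: MotionTrace, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.t_s, "value": trace.value})
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_trace_csv(path: str | Path, stage: TraceStage = TraceStage.RAW) -> MotionTrace:
    df = pd.read_csv(path)
    if not {"time_s", "value"} <= set(df.columns):
        raise ValueError(f"{path}: trace CSV needs columns time_s, value")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError(f"{path}: trace must be uniformly sampled")
    fps = 1.0 / dt[0] if len(dt) else 30.0
    return MotionTrace(value=df["value"].to_numpy(), fps=fps, stage=stage)


def write_metrics_json(metrics: CycleMetrics, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(metrics.as_dict(), indent=2, sort_keys=True) + "\n")
    return path


def write_ground_truth(gt: GroundTruth, path_prefix: str | Path) -> tuple[Path, Path]:
    """Ground truth as a JSON summary plus a per-frame CSV side-car."""
    prefix = Path(path_prefix)
    summary = {
        "true_period_s": gt.true_period_s,
        "true_contraction_s": gt.true_contraction_s,
        "true_relaxation_s": gt.true_relaxation_s,
        "stimulus_frames": gt.stimulus_frames.tolist(),
        "n_frames": len(gt.apex_height_trace),
    }
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    csv_path = prefix.with_suffix(".csv")
    pd.DataFrame(
        {
            "frame": np.arange(len(gt.apex_height_trace)),
            "apex_height_mm": gt.apex_height_trace,
            "stretch_pct": gt.true_stretch_trace,
        }
    ).to_csv(csv_path, index=False, float_format="%.9g")
    return json_path, csv_path


def write_waveform_csv(waveform, schedule, path: str | Path) -> Path:
    """Pressure waveform + stimulus marker as CSV.

    Columns: time_s, pressure_mmHg, phase, stimulus (0/1; 1 while the
    pulse is active).
    """
    path = Path(path)
    stim = np.zeros(len(waveform.t), dtype=int)
    dur_s = schedule.duration_ms * 1e-3
    for onset in schedule.onset_times_s:
        stim[(waveform.t >= onset) & (waveform.t < onset + dur_s)] = 1
    pd.DataFrame(
        {
            "time_s": waveform.t,
            "pressure_mmHg": waveform.p,
            "phase": waveform.phase,
            "stimulus": stim,
        }
    ).to_csv(path, index=False, float_format="%.9g")
    return path
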