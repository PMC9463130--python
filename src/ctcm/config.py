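"""YAML configuration for the analysis pipeline.

A config file holds one section per stage (``cycle``, ``scene``, ``trace``,
``strain``, ``io``) plus a global ``seed``; every field has a documented
default, unknown keys are rejected by name, and a loaded config round-trips
losslessly through :func:`save_config`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .device_cycle import CycleParams
from .synthetic import SceneParams

__all__ = ["TraceConfig", "StrainConfig", "IOConfig", "PipelineConfig",
           "load_config", "save_config"]


@dataclass(frozen=True)
class TraceConfig:
    """Filter / detrend / peak-analysis parameters."""

    cutoff_hz: float = 5.0
    detrend_order: int = 6
    min_prominence_frac: float = 0.3
    min_separation_s: float = 0.4
    ref_index: int = 0

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError("trace.cutoff_hz must be positive")
        if self.detrend_order < 0:
            raise ValueError("trace.detrend_order must be non-negative")
        if not 0 < self.min_prominence_frac <= 1:
            raise ValueError("trace.min_prominence_frac must lie in (0, 1]")


@dataclass(frozen=True)
class StrainConfig:
    """Shape-from-shading and region-partition parameters.

    The default light direction matches the recording geometry of an
    obliquely mounted camera rig (51 degrees off vertical).
    """

    n_regions: int = 10
    n_iter: int = 60
    light_zenith_deg: float = 51.0
    light_azimuth_deg: float = 0.0
    albedo_from_down: bool = True
    min_area_px: int = 64

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("strain.n_regions must be positive")
        if not 0 <= self.light_zenith_deg < 90:
            raise ValueError("strain.light_zenith_deg must lie in [0, 90)")


@dataclass(frozen=True)
class IOConfig:
    """Input/output paths and formats."""

    video: str = ""
    mask: str = ""
    out_dir: str = "out"
    video_format: str = "tiff"  # tiff | avi


@dataclass(frozen=True)
class PipelineConfig:
    cycle: CycleParams = field(default_factory=CycleParams)
    scene: SceneParams = field(default_factory=SceneParams)
    trace: TraceConfig = field(default_factory=TraceConfig)
    strain: StrainConfig = field(default_factory=StrainConfig)
    io: IOConfig = field(default_factory=IOConfig)
    seed: int = 0


_SECTIONS = {
    "cycle": CycleParams,
    "scene": SceneParams,
    "trace": TraceConfig,
    "strain": StrainConfig,
    "io": IOConfig,
}


def _build_section(name: str, cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) in section '{name}': {', '.join(sorted(unknown))}"
        )
    # YAML gives lists where the dataclasses expect tuples
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    try:
        return cls(**coerced)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid value in section '{name}': {exc}") from exc


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Missing sections and fields take their defaults; unknown keys raise a
    configuration error naming the offending key.  ``path=None`` (or an
    empty file) yields the all-defaults configuration.
    """
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    sections = {
        name: _build_section(name, cls, raw.get(name) or {})
        for name, cls in _SECTIONS.items()
    }
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ValueError(f"seed must be an integer, got {seed!r}")
    return PipelineConfig(seed=seed, **sections)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (full round-trip of every field)."""
    data = {name: asdict(getattr(config, name)) for name in _SECTIONS}
    data["seed"] = config.seed
    for section in data.values():
        if isinstance(section, dict):
            for k, v in section.items():
                if isinstance(v, tuple):
                    section[k] = list(v)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
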