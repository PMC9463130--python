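"""Cardiac-cycle simulation for the pneumatic tissue-culture device.

The device distends a thin silicone membrane under a 7-mm ring aperture by
cycling the air-chamber pressure at 1.2 Hz (72 beats per minute), with a
60 % rising (diastolic) and 40 % falling (systolic) fraction.  Electrical
field stimulation is triggered on the rising pressure limb so that the
pulse lands a fixed lead time (default 100 ms) before the systolic phase.

This module provides

* the pressure waveform and the threshold-based stimulus scheduler,
* a spherical-cap model of the distended membrane, with the arc-over-chord
  percent-stretch operator and its inverse,
* a monotone pressure->apex-height calibration, and
* the slice oversizing geometry (cut diameter for a target excess area).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "CycleParams",
    "PressureWaveform",
    "StimulusSchedule",
    "CapGeometry",
    "CalibrationMap",
    "generate_pressure_waveform",
    "schedule_stimulation",
    "cap_from_height",
    "percent_stretch",
    "height_for_stretch",
    "default_calibration",
    "pressure_to_height",
    "oversize_cut_diameter",
]

#: phase labels used throughout the package
DIASTOLE = "diastole"
SYSTOLE = "systole"


@dataclass(frozen=True)
class CycleParams:
    """Parameters of one emulated cardiac cycle.

    Defaults reproduce the device's physiological regime: 1.2 Hz pacing,
    40 % systole / 60 % diastole, 80 mmHg peak air-chamber pressure
    (140 mmHg in the overstretch regime), and a 2 ms, 4 V biphasic pulse
    initiated 100 ms before the systolic phase.
    """

    period_s: float = 1.0 / 1.2
    systole_fraction: float = 0.40
    peak_pressure_mmHg: float = 80.0
    baseline_pressure_mmHg: float = 0.0
    stim_lead_ms: float = 100.0
    stim_duration_ms: float = 2.0
    stim_amplitude_V: float = 4.0
    n_cycles: int = 3
    sample_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError(f"period_s must be positive, got {self.period_s}")
        if not 0 < self.systole_fraction < 1:
            raise ValueError(
                f"systole_fraction must lie in (0, 1), got {self.systole_fraction}"
            )
        if self.peak_pressure_mmHg <= self.baseline_pressure_mmHg:
            raise ValueError("peak pressure must exceed baseline pressure")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be a positive integer")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        diastole_ms = (1.0 - self.systole_fraction) * self.period_s * 1e3
        if not 0 <= self.stim_lead_ms < diastole_ms:
            raise ValueError(
                f"stim_lead_ms ({self.stim_lead_ms}) must be shorter than the "
                f"diastolic duration ({diastole_ms:.1f} ms)"
            )

    @property
    def diastole_s(self) -> float:
        """Duration of the rising (filling/stretch) segment."""
        return (1.0 - self.systole_fraction) * self.period_s

    @property
    def systole_s(self) -> float:
        """Duration of the falling (contraction) segment."""
        return self.systole_fraction * self.period_s

    def overstretch(self) -> "CycleParams":
        """Return a copy in the 140 mmHg overstretch regime."""
        return replace(self, peak_pressure_mmHg=140.0)


@dataclass(frozen=True)
class PressureWaveform:
    """Sampled air-chamber pressure with per-sample phase labels."""

    t: np.ndarray  # seconds, uniform grid
    p: np.ndarray  # mmHg
    phase: np.ndarray  # str array, "diastole" | "systole"
    params: CycleParams

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.p) == len(self.phase)):
            raise ValueError("t, p and phase must have equal length")

    @property
    def sample_rate_hz(self) -> float:
        return self.params.sample_rate_hz

    def systole_onsets_s(self) -> np.ndarray:
        """Times at which each cycle switches from diastole to systole."""
        n = np.arange(self.params.n_cycles)
        return n * self.params.period_s + self.params.diastole_s


@dataclass(frozen=True)
class StimulusSchedule:
    """Electrical stimulation onsets derived from a pressure threshold."""

    onset_times_s: np.ndarray
    duration_ms: float
    amplitude_V: float
    threshold_mmHg: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.onset_times_s) <= 0):
            raise ValueError("stimulus onsets must be strictly increasing")


@dataclass(frozen=True)
class CapGeometry:
    """Spherical cap over a circular ring aperture.

    ``a`` is the ring radius, ``h`` the apex height; ``R`` the radius of the
    sphere through the cap, and ``theta`` the half-opening angle, so that
    ``R = (a^2 + h^2) / (2 h)`` and ``sin(theta) = a / R``.
    """

    ring_radius_mm: float
    apex_height_mm: float
    sphere_radius_mm: float
    half_angle_rad: float


@dataclass(frozen=True)
class CalibrationMap:
    """Monotone (pressure mmHg, apex height mm) anchor pairs.

    The device reports pressures and the stretch they produce but no
    intermediate deflection curve, so the mapping is pinned at measured
    anchors and interpolated with a monotone piecewise cubic (PCHIP).
    """

    anchors: tuple[tuple[float, float], ...]
    _interp: PchipInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.anchors, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ValueError("need at least two (pressure, height) anchors")
        if np.any(np.diff(pts[:, 0]) <= 0) or np.any(np.diff(pts[:, 1]) <= 0):
            raise ValueError("anchors must be strictly increasing in both coordinates")
        object.__setattr__(self, "_interp", PchipInterpolator(pts[:, 0], pts[:, 1]))

    @property
    def pressure_range(self) -> tuple[float, float]:
        return self.anchors[0][0], self.anchors[-1][0]


def generate_pressure_waveform(params: CycleParams) -> PressureWaveform:
    """Sample the cyclic air-chamber pressure.

    Each cycle is a raised-cosine rise from baseline to peak over the
    diastolic fraction followed by a raised-cosine fall back to baseline
    over the systolic fraction; the two half-cosines meet with zero slope,
    so the trace is C1-continuous with a single maximum per cycle.
    """
    dt = 1.0 / params.sample_rate_hz
    n = int(round(params.n_cycles * params.period_s * params.sample_rate_hz))
    t = np.arange(n) * dt
    tc = np.mod(t, params.period_s)  # time within the cycle
    amp = params.peak_pressure_mmHg - params.baseline_pressure_mmHg

    rising = tc < params.diastole_s
    p = np.empty(n)
    p[rising] = 0.5 * (1.0 - np.cos(np.pi * tc[rising] / params.diastole_s))
    p[~rising] = 0.5 * (
        1.0 + np.cos(np.pi * (tc[~rising] - params.diastole_s) / params.systole_s)
    )
    p = params.baseline_pressure_mmHg + amp * p

    phase = np.where(rising, DIASTOLE, SYSTOLE)
    return PressureWaveform(t=t, p=p, phase=phase, params=params)


def schedule_stimulation(
    waveform: PressureWaveform, params: CycleParams | None = None
) -> StimulusSchedule:
    """Derive the stimulation schedule from rising-limb threshold crossings.

    The trigger threshold is the pressure on the rising limb a lead time
    (``stim_lead_ms``) before the systolic onset; onsets are detected by
    sample-wise comparison of the waveform against that threshold, rising
    edges only, so each onset precedes its cycle's systole by the lead time
    to within one sample period.
    """
    params = params or waveform.params
    lead_s = params.stim_lead_ms * 1e-3
    t_thr = params.diastole_s - lead_s  # cycle time of the crossing
    amp = params.peak_pressure_mmHg - params.baseline_pressure_mmHg
    threshold = params.baseline_pressure_mmHg + amp * 0.5 * (
        1.0 - np.cos(np.pi * t_thr / params.diastole_s)
    )

    # sample-wise below->above transitions; with a single maximum per cycle
    # these occur on the rising limb only
    above = waveform.p >= threshold
    prev_below = np.concatenate(([True], ~above[:-1]))
    crossings = np.flatnonzero(above & prev_below)
    if crossings.size == 0:
        raise RuntimeError(
            f"stimulation threshold {threshold:.2f} mmHg never crossed on a rising limb"
        )
    # one onset per cycle: first crossing in each period
    cycle_idx = (waveform.t[crossings] // params.period_s).astype(int)
    _, first = np.unique(cycle_idx, return_index=True)
    onsets = waveform.t[crossings[first]]
    return StimulusSchedule(
        onset_times_s=onsets,
        duration_ms=params.stim_duration_ms,
        amplitude_V=params.stim_amplitude_V,
        threshold_mmHg=float(threshold),
    )


def cap_from_height(a: float, h: float) -> CapGeometry:
    """Spherical-cap geometry from ring radius ``a`` and apex height ``h`` (mm).

    ``h = 0`` is the flat limit (theta -> 0, sphere radius -> inf); heights
    above ``a`` (beyond the hemisphere) are outside the device's regime and
    rejected.
    """
    if a <= 0:
        raise ValueError(f"ring radius must be positive, got {a}")
    if not 0 <= h <= a:
        raise ValueError(f"apex height must lie in [0, {a}] mm, got {h}")
    if h == 0:
        return CapGeometry(a, 0.0, np.inf, 0.0)
    R = (a * a + h * h) / (2.0 * h)
    theta = np.arcsin(min(1.0, a / R))
    return CapGeometry(a, h, R, float(theta))


def percent_stretch(cap: CapGeometry) -> float:
    """Arc-over-chord elongation of the cap cross-section, in percent.

    The rest length of the membrane profile across the ring is the chord
    (the ring diameter ``2a``); distended, the same material spans the arc
    ``2 R theta``.  Percent stretch is ``100 (theta / sin(theta) - 1)``,
    which is 0 in the flat limit and strictly increasing in apex height.
    """
    theta = cap.half_angle_rad
    if theta == 0:
        return 0.0
    return 100.0 * (theta / np.sin(theta) - 1.0)


def height_for_stretch(target_percent: float, a: float = 3.5) -> float:
    """Invert :func:`percent_stretch`: apex height giving a target stretch.

    Solved by bracketed root finding on ``[0, a]``; targets at or beyond the
    hemispherical limit (~57.1 %) are unreachable.
    """
    if target_percent < 0:
        raise ValueError("target stretch must be non-negative")
    if target_percent == 0:
        return 0.0
    max_pct = percent_stretch(cap_from_height(a, a))
    if target_percent >= max_pct:
        raise ValueError(
            f"target stretch {target_percent}% is outside the achievable "
            f"range [0, {max_pct:.1f}%) for a cap"
        )
    return float(
        brentq(
            lambda h: percent_stretch(cap_from_height(a, h)) - target_percent,
            1e-12,
            a,
            xtol=1e-12,
            rtol=1e-14,
        )
    )


def default_calibration(
    a: float = 3.5,
    baseline_mmHg: float = 0.0,
) -> CalibrationMap:
    """Calibration anchored at the device's two characterised regimes.

    80 mmHg produces a 25 % stretch and 140 mmHg a 32 % stretch of the
    slice; the corresponding apex heights pin the pressure->height curve,
    with (baseline, 0) as the resting anchor.
    """
    return CalibrationMap(
        anchors=(
            (baseline_mmHg, 0.0),
            (80.0, height_for_stretch(25.0, a)),
            (140.0, height_for_stretch(32.0, a)),
        )
    )


def pressure_to_height(p, cal: CalibrationMap):
    """Map pressure (mmHg) to membrane apex height (mm) via the calibration.

    Monotone piecewise-cubic interpolation through the anchors, exact at
    each anchor; pressures outside the anchored range are refused rather
    than extrapolated.
    """
    p_arr = np.asarray(p, dtype=float)
    lo, hi = cal.pressure_range
    if np.any(p_arr < lo - 1e-12) or np.any(p_arr > hi + 1e-12):
        raise ValueError(
            f"pressure outside calibrated range [{lo}, {hi}] mmHg"
        )
    out = cal._interp(np.clip(p_arr, lo, hi))
    return float(out) if np.isscalar(p) else out


def oversize_cut_diameter(ring_diameter: float, area_fraction: float = 0.25) -> float:
    """Cut diameter for a slice oversized by a fraction of the ring area.

    A slice cut ``area_fraction`` larger in area than the support ring has
    diameter ``d * sqrt(1 + area_fraction)``; the default 25 % excess keeps
    the tissue slack enough not to overstretch at diastolic distension.
    """
    if ring_diameter <= 0:
        raise ValueError("ring diameter must be positive")
    if area_fraction < 0:
        raise ValueError("area fraction must be non-negative")
    return ring_diameter * float(np.sqrt(1.0 + area_fraction))
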