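"""Synthetic beating-tissue recordings with known ground truth.

Renders a ring-mounted tissue slice distending as a spherical membrane cap
under the device pressure cycle, shaded with a Lambertian model under a
known light direction, with a seeded smooth albedo texture, additive
Gaussian sensor noise, and optional slow baseline drift.  Every clip comes
with per-frame ground truth (apex height, percent stretch, cycle timing),
so the motion-trace and strain pipelines can be tested end to end without
any recorded video.

Rendering is orthographic and top-down; the oblique recording geometry of
a real camera rig can be approximated by an affine shear but is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .device_cycle import (
    CalibrationMap,
    CapGeometry,
    CycleParams,
    cap_from_height,
    default_calibration,
    generate_pressure_waveform,
    height_for_stretch,
    percent_stretch,
    pressure_to_height,
    schedule_stimulation,
)

__all__ = [
    "SceneParams",
    "GroundTruth",
    "VideoClip",
    "render_height_field",
    "make_albedo",
    "lambertian_render",
    "simulate_recording",
    "simulate_trace",
    "simulate_stim_pair",
]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("light direction must be non-zero")
    return v / n


@dataclass(frozen=True)
class SceneParams:
    """Rendering geometry and sensor model for synthetic recordings.

    ``mm_per_px`` sizes the 7-mm ring inside the frame; the default light
    leans 20 degrees off vertical so shading encodes surface slope without
    deep shadows.  ``noise_sd`` is the Gaussian sensor noise standard
    deviation as a fraction of the [0, 1] dynamic range.  ``albedo_contrast``
    is the peak-to-peak amplitude of the smooth seeded reflectance texture
    inside the tissue.
    """

    image_size_px: tuple[int, int] = (256, 256)
    mm_per_px: float = 8.0 / 256.0
    light_direction: tuple[float, float, float] = (
        float(np.sin(np.deg2rad(20.0))),
        0.0,
        float(np.cos(np.deg2rad(20.0))),
    )
    albedo_texture_seed: int = 0
    albedo_mean: float = 0.85
    albedo_contrast: float = 0.10
    background_albedo: float = 0.05
    noise_sd: float = 0.0
    fps: float = 30.0
    drift_coeffs: tuple[float, ...] = ()
    camera_tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        L = _unit(self.light_direction)
        if L[2] <= 0:
            raise ValueError("light direction must have a positive vertical component")
        object.__setattr__(self, "light_direction", tuple(float(v) for v in L))

    @property
    def light(self) -> np.ndarray:
        return np.asarray(self.light_direction)


@dataclass
class GroundTruth:
    """Generator-side truth accompanying a synthetic clip or trace."""

    apex_height_trace: np.ndarray  # mm per frame
    true_stretch_trace: np.ndarray  # percent per frame
    true_period_s: float
    true_contraction_s: float  # systolic (falling) segment
    true_relaxation_s: float  # diastolic (rising) segment
    stimulus_frames: np.ndarray = field(default_factory=lambda: np.array([], int))
    per_frame_height_fields: np.ndarray | None = None  # (n_frames, rows, cols) mm

    def __post_init__(self) -> None:
        if len(self.apex_height_trace) != len(self.true_stretch_trace):
            raise ValueError("ground-truth traces must have equal length")
        if not np.isclose(
            self.true_contraction_s + self.true_relaxation_s, self.true_period_s
        ):
            raise ValueError("contraction + relaxation must equal the period")


@dataclass(frozen=True)
class VideoClip:
    """Stack of grayscale frames with intensities in [0, 1]."""

    frames: np.ndarray  # (n_frames, rows, cols)
    fps: float
    mm_per_px: float

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def render_height_field(cap: CapGeometry, scene: SceneParams) -> np.ndarray:
    """Height map (mm) of the spherical cap over the ring aperture.

    ``z(x, y) = sqrt(R^2 - r^2) - (R - h)`` for radial distance ``r <= a``
    from the image centre (in mm); zero outside the aperture.
    """
    rows, cols = scene.image_size_px
    a = cap.ring_radius_mm
    half_extent = min(rows, cols) * scene.mm_per_px / 2.0
    if a > half_extent:
        raise ValueError(
            f"ring radius {a} mm does not fit in a "
            f"{rows}x{cols} px frame at {scene.mm_per_px:.4f} mm/px"
        )
    y = (np.arange(rows) - (rows - 1) / 2.0) * scene.mm_per_px
    x = (np.arange(cols) - (cols - 1) / 2.0) * scene.mm_per_px
    r2 = x[None, :] ** 2 + y[:, None] ** 2
    z = np.zeros((rows, cols))
    if cap.apex_height_mm > 0:
        R = cap.sphere_radius_mm
        inside = r2 <= a * a
        z[inside] = np.sqrt(R * R - r2[inside]) - (R - cap.apex_height_mm)
    return z


def ring_mask(scene: SceneParams, a: float = 3.5) -> np.ndarray:
    """Boolean mask of the ring aperture (the tissue region)."""
    rows, cols = scene.image_size_px
    y = (np.arange(rows) - (rows - 1) / 2.0) * scene.mm_per_px
    x = (np.arange(cols) - (cols - 1) / 2.0) * scene.mm_per_px
    return x[None, :] ** 2 + y[:, None] ** 2 <= a * a


def make_albedo(scene: SceneParams, a: float = 3.5) -> np.ndarray:
    """Seeded band-limited reflectance texture inside the ring, dark outside.

    Smooth multiplicative texture stands in for the uneven reflectance of
    tissue; the dark background makes the slice segmentable the way a real
    recording's dim chamber floor is.
    """
    rows, cols = scene.image_size_px
    rng = np.random.default_rng(scene.albedo_texture_seed)
    noise = rng.standard_normal((rows, cols))
    smooth = gaussian_filter(noise, sigma=min(rows, cols) / 16.0)
    span = smooth.max() - smooth.min()
    if span > 0:
        smooth = (smooth - smooth.min()) / span - 0.5
    texture = scene.albedo_mean + scene.albedo_contrast * smooth
    albedo = np.full((rows, cols), scene.background_albedo)
    inside = ring_mask(scene, a)
    albedo[inside] = texture[inside]
    return albedo


def lambertian_render(
    height: np.ndarray, scene: SceneParams, albedo: np.ndarray | float = 1.0
) -> np.ndarray:
    """Shade a height map: ``I = albedo * max(0, n . L)``, clipped to [0, 1].

    Surface normals come from central-difference gradients of the height
    map (spacing ``mm_per_px``), matching the Lambertian assumption of the
    shape-from-shading reconstruction.
    """
    if not np.all(np.isfinite(height)):
        raise ValueError("height field must be finite")
    dz_dy, dz_dx = np.gradient(height, scene.mm_per_px)
    L = scene.light
    norm = np.sqrt(1.0 + dz_dx**2 + dz_dy**2)
    shading = (-dz_dx * L[0] - dz_dy * L[1] + L[2]) / norm
    frame = np.asarray(albedo) * np.maximum(shading, 0.0)
    return np.clip(frame, 0.0, 1.0)


def _drift(t: np.ndarray, coeffs, duration_s: float) -> np.ndarray:
    """Slow baseline drift: polynomial in normalised time t/duration."""
    if coeffs is None or len(coeffs) == 0:
        return np.zeros_like(t)
    return np.polynomial.polynomial.polyval(t / duration_s, np.asarray(coeffs))


def _height_trace(
    cycle: CycleParams, cal: CalibrationMap, fps: float, duration_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame membrane apex height (mm) over the recording."""
    n_frames = int(round(duration_s * fps))
    t = np.arange(n_frames) / fps
    tc = np.mod(t, cycle.period_s)
    amp = cycle.peak_pressure_mmHg - cycle.baseline_pressure_mmHg
    rising = tc < cycle.diastole_s
    p = np.empty(n_frames)
    p[rising] = 0.5 * (1.0 - np.cos(np.pi * tc[rising] / cycle.diastole_s))
    p[~rising] = 0.5 * (
        1.0 + np.cos(np.pi * (tc[~rising] - cycle.diastole_s) / cycle.systole_s)
    )
    p = cycle.baseline_pressure_mmHg + amp * p
    return t, pressure_to_height(p, cal)


def _stimulus_frames(cycle: CycleParams, fps: float, duration_s: float) -> np.ndarray:
    wf = generate_pressure_waveform(cycle)
    sched = schedule_stimulation(wf, cycle)
    per_cycle_onset = float(np.mod(sched.onset_times_s[0], cycle.period_s))
    n_cycles = int(duration_s / cycle.period_s)
    onsets = per_cycle_onset + np.arange(n_cycles) * cycle.period_s
    frames = np.round(onsets * fps).astype(int)
    return frames[frames < int(round(duration_s * fps))]


def _ground_truth(
    cycle: CycleParams, heights: np.ndarray, fps: float, duration_s: float
) -> GroundTruth:
    a = 3.5
    stretch = np.array([percent_stretch(cap_from_height(a, h)) for h in heights])
    return GroundTruth(
        apex_height_trace=heights,
        true_stretch_trace=stretch,
        true_period_s=cycle.period_s,
        true_contraction_s=cycle.systole_s,
        true_relaxation_s=cycle.diastole_s,
        stimulus_frames=_stimulus_frames(cycle, fps, duration_s),
    )


def simulate_recording(
    cycle: CycleParams,
    scene: SceneParams,
    cal: CalibrationMap | None = None,
    seed: int = 0,
    duration_s: float = 10.0,
    keep_height_fields: bool = False,
) -> tuple[VideoClip, GroundTruth]:
    """Render a full synthetic recording of the distending slice.

    Per frame: pressure -> apex height (calibration) -> spherical-cap height
    field -> Lambertian shading with the seeded albedo texture -> additive
    Gaussian noise -> clip to [0, 1].  Identical parameters and seed give
    bit-identical output.
    """
    cal = cal or default_calibration()
    a = 3.5
    t, heights = _height_trace(cycle, cal, scene.fps, duration_s)
    albedo = make_albedo(scene, a)
    rng = np.random.default_rng(seed)
    frames = np.empty((len(t), *scene.image_size_px))
    height_fields = (
        np.empty((len(t), *scene.image_size_px)) if keep_height_fields else None
    )
    for k, h in enumerate(heights):
        z = render_height_field(cap_from_height(a, h), scene)
        if height_fields is not None:
            height_fields[k] = z
        frame = lambertian_render(z, scene, albedo)
        if scene.noise_sd > 0:
            frame = frame + rng.normal(0.0, scene.noise_sd, frame.shape)
        frames[k] = np.clip(frame, 0.0, 1.0)

    gt = _ground_truth(cycle, heights, scene.fps, duration_s)
    gt.per_frame_height_fields = height_fields
    clip = VideoClip(frames=frames, fps=scene.fps, mm_per_px=scene.mm_per_px)
    return clip, gt


def simulate_trace(
    cycle: CycleParams,
    noise_sd: float = 0.0,
    drift_coeffs=(),
    duration_s: float = 20.0,
    fps: float = 30.0,
    seed: int = 0,
    cal: CalibrationMap | None = None,
):
    """Fast 1-D movement-trace fixture, bypassing rendering.

    The movement signal is proportional to the membrane apex height, plus a
    polynomial baseline drift (coefficients in signal units, evaluated in
    normalised time) and seeded Gaussian noise.  Ground-truth timing is
    exact.  Returns ``(t_s, value, GroundTruth)``.
    """
    if duration_s < 3 * cycle.period_s:
        raise ValueError("duration must cover at least 3 cycles")
    cal = cal or default_calibration()
    t, heights = _height_trace(cycle, cal, fps, duration_s)
    rng = np.random.default_rng(seed)
    value = heights + _drift(t, drift_coeffs, duration_s)
    if noise_sd > 0:
        value = value + rng.normal(0.0, noise_sd, value.shape)
    gt = _ground_truth(cycle, heights, fps, duration_s)
    return t, value, gt


def simulate_stim_pair(
    cycle: CycleParams,
    scene: SceneParams,
    stim_stretch_pct: float = 25.0,
    unstim_stretch_pct: float = 20.833,
    seed: int = 0,
    duration_s: float = 10.0,
):
    """Paired recordings differing only in peak stretch.

    Emulates imaging the same slice with and without electrical pacing:
    identical scene, albedo texture and noise stream, but peak membrane
    deflections set by ``height_for_stretch`` of each target stretch.
    Returns ``(clip_stim, clip_unstim, gt_stim, gt_unstim)``.
    """
    if not stim_stretch_pct >= unstim_stretch_pct >= 0:
        raise ValueError(
            "stimulated stretch must be >= unstimulated stretch >= 0"
        )

    def _cal_for(pct: float) -> CalibrationMap | None:
        if pct == 0:
            return None
        h = height_for_stretch(pct, 3.5)
        return CalibrationMap(
            anchors=((cycle.baseline_pressure_mmHg, 0.0), (cycle.peak_pressure_mmHg, h))
        )

    out = []
    for pct in (stim_stretch_pct, unstim_stretch_pct):
        cal = _cal_for(pct)
        if cal is None:
            # static clip: flat membrane throughout
            n = int(round(duration_s * scene.fps))
            albedo = make_albedo(scene)
            frame = lambertian_render(np.zeros(scene.image_size_px), scene, albedo)
            frames = np.repeat(frame[None], n, axis=0)
            if scene.noise_sd > 0:
                rng = np.random.default_rng(seed)
                frames = np.clip(
                    frames + rng.normal(0.0, scene.noise_sd, frames.shape), 0.0, 1.0
                )
            clip = VideoClip(frames, scene.fps, scene.mm_per_px)
            gt = _ground_truth(cycle, np.zeros(n), scene.fps, duration_s)
        else:
            clip, gt = simulate_recording(cycle, scene, cal, seed, duration_s)
        out.append((clip, gt))
    (clip_s, gt_s), (clip_u, gt_u) = out
    return clip_s, clip_u, gt_s, gt_u
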