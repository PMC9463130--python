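"""Optical regional strain from Up/Down frames of a beating-slice video.

The contractile state of a ring-mounted slice is read out optically: the
movement trace picks the most-distended (Up) and least-distended (Down)
frames, the tissue is segmented, relative surface heights are recovered by
an iterative linearized Lambertian shape-from-shading scheme (regularized
Gauss-Newton with a membrane prior, see :func:`shape_from_shading`), the
mask is partitioned into ten bands along its principal axis,
and each band's strain is ``(S_up - S_down) / S_down`` where ``S`` is the
mean 3-D transect path length across the band.  A paired comparison then
contrasts stimulated and unstimulated recordings region by region.

Shape-from-shading heights are relative; both frames of a pair are
reconstructed with identical settings so the unknown global scale is
shared.  When the Down frame is close to flat (membrane at rest) it also
serves as an albedo reference, which removes the reflectance texture
before reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse, stats
from scipy.sparse import linalg as splinalg
from skimage import filters, measure

from .motion import MotionTrace, PeakSet
from .synthetic import VideoClip

__all__ = [
    "RegionSet",
    "RegionalStrainResult",
    "StimComparison",
    "segment_tissue",
    "select_extreme_frames",
    "shape_from_shading",
    "partition_regions",
    "regional_surface_distance",
    "regional_strain",
    "moving_regions",
    "compare_stim",
    "analyze_strain_pair",
]


@dataclass(frozen=True)
class RegionSet:
    """Partition of a mask into ordered bands along its principal axis."""

    labels: np.ndarray  # 0 outside mask, 1..n inside
    n_regions: int
    axis_angle_rad: float  # principal-axis angle w.r.t. image x-axis

    def region_mask(self, r: int) -> np.ndarray:
        if not 1 <= r <= self.n_regions:
            raise IndexError(f"region {r} out of range 1..{self.n_regions}")
        return self.labels == r


@dataclass(frozen=True)
class RegionalStrainResult:
    """Per-region surface distances and strain for an Up/Down frame pair."""

    s_up: np.ndarray  # length units, per region
    s_down: np.ndarray
    strain: np.ndarray  # (s_up - s_down) / s_down
    up_frame: int
    down_frame: int


@dataclass(frozen=True)
class StimComparison:
    """Region-wise paired contrast of two conditions."""

    percent_difference: np.ndarray  # 100 * (mean_stim - mean_nostim) / mean_nostim
    t_statistic: np.ndarray
    p_value: np.ndarray
    n_pairs: int


def segment_tissue(frame: np.ndarray, min_area_px: int = 64) -> np.ndarray:
    """Segment the tissue as the largest bright connected component.

    Otsu global threshold, largest connected foreground component, holes
    filled.  Fails if no component reaches ``min_area_px`` or if the frame
    has no separable foreground (e.g. uniform intensity).
    """
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0:
        raise ValueError("frame has uniform intensity; nothing to segment")
    thr = filters.threshold_otsu(frame)
    fg = frame > thr
    labels = measure.label(fg)
    if labels.max() == 0:
        raise ValueError("no foreground component found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = int(sizes.argmax())
    if sizes[best] < min_area_px:
        raise ValueError(
            f"largest component has {sizes[best]} px, below min_area_px={min_area_px}"
        )
    return ndimage.binary_fill_holes(labels == best)


def select_extreme_frames(trace: MotionTrace, peaks: PeakSet) -> tuple[int, int]:
    """Frames of extreme movement: (Up, Down).

    Up is the peak with the globally largest trace value, Down the valley
    with the smallest.
    """
    if peaks.peak_indices.size == 0 or peaks.valley_indices.size == 0:
        raise ValueError("need at least one peak and one valley")
    up = int(peaks.peak_indices[np.argmax(trace.value[peaks.peak_indices])])
    down = int(peaks.valley_indices[np.argmin(trace.value[peaks.valley_indices])])
    return up, down


def _difference_operators(rows: int, cols: int):
    """Sparse central-difference operators matching ``np.gradient``."""

    def d1(n):
        D = sparse.diags(
            [-0.5 * np.ones(n - 1), np.zeros(n), 0.5 * np.ones(n - 1)],
            [-1, 0, 1],
            format="lil",
        )
        D[0, 0], D[0, 1] = -1, 1
        D[n - 1, n - 2], D[n - 1, n - 1] = -1, 1
        return D

    Dx = sparse.kron(sparse.eye(rows), d1(cols)).tocsr()
    Dy = sparse.kron(d1(rows), sparse.eye(cols)).tocsr()
    return Dx, Dy


def _laplacian_5pt(rows: int, cols: int):
    """Standard 5-point Laplacian (Neumann edges).

    Unlike an operator composed from central differences, this stencil
    penalizes single-pixel (checkerboard) oscillations, which the central-
    difference photometric term cannot see.
    """

    def d_fwd(n):
        D = sparse.diags([-np.ones(n), np.ones(n - 1)], [0, 1], format="lil")
        D[n - 1, n - 1] = 0
        return D

    Fx = sparse.kron(sparse.eye(rows), d_fwd(cols)).tocsr()
    Fy = sparse.kron(d_fwd(rows), sparse.eye(cols)).tocsr()
    return (Fx.T @ Fx + Fy.T @ Fy).tocsr()


def _membrane_mode(mask: np.ndarray, Lm, idx) -> np.ndarray:
    """Unit-apex deflection of a clamped linear membrane over the mask.

    Solves ``-laplacian(z) = const`` with z = 0 outside the mask — the
    small-deflection shape of a uniformly pressurized membrane clamped at
    the tissue boundary.
    """
    zf, _ = splinalg.cg(Lm[:, idx], np.ones(len(idx)), rtol=1e-6, maxiter=3000)
    z = np.zeros(mask.size)
    z[idx] = np.maximum(zf, 0.0)
    z = z.reshape(mask.shape)
    peak = z.max()
    return z / peak if peak > 0 else z


def shape_from_shading(
    frame: np.ndarray,
    mask: np.ndarray,
    light_direction,
    n_iter: int = 60,
    albedo: np.ndarray | None = None,
    smoothness: float = 0.3,
    smoothness_floor: float = 1e-6,
) -> np.ndarray:
    """Recover relative surface heights from a single shaded image.

    Iterative linearized Lambertian scheme: heights over the mask are found
    by damped Gauss-Newton on the photometric residual ``I - R(grad z)``
    (central-difference gradients, reflectance under the known light
    direction), with a curvature-variation regularizer ``|lap z - mean|^2``
    whose weight anneals from ``smoothness`` down to ``smoothness_floor``.
    Single-image shape from shading has a concave/convex ambiguity; it is
    resolved here with the physical prior that the tissue distends upward
    as a pressurized membrane clamped at its boundary: the solver starts
    from the clamped-membrane mode with the amplitude that best explains
    the image photometrically (amplitude 0 — flat — for a featureless
    frame), then refines freely.

    Heights are in pixel units (multiply by the pixel pitch for physical
    units), relative to the in-mask minimum, zero outside the mask, and
    deterministic for fixed inputs and ``n_iter``.
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if frame.shape != mask.shape:
        raise ValueError("frame and mask shapes differ")
    L = np.asarray(light_direction, dtype=float)
    L = L / np.linalg.norm(L)
    if L[2] <= 0:
        raise ValueError("light direction must have a positive vertical component")

    E = frame
    if albedo is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            E = np.where(np.asarray(albedo) > 1e-6, frame / albedo, 0.0)
    rows, cols = E.shape
    e = np.clip(E, 0.0, 1.0).ravel().copy()
    free = mask.ravel()
    e[~free] = L[2]  # flat background outside the tissue
    idx = np.flatnonzero(free)
    nf = len(idx)

    Dx, Dy = _difference_operators(rows, cols)
    Lap = _laplacian_5pt(rows, cols)
    Lm = Lap[idx]

    def photometric(z):
        p, q = Dx @ z, Dy @ z
        s = np.sqrt(1.0 + p * p + q * q)
        R = (-p * L[0] - q * L[1] + L[2]) / s
        return R - e, p, q, s, R

    def cost(z, lam):
        r = photometric(z)[0]
        B = Lm @ z
        Bc = B - B.mean()
        return 0.5 * float(r @ r) + 0.5 * lam * float(Bc @ Bc)

    # membrane-prior initialization: scan the one-parameter family
    mode = _membrane_mode(mask, Lm, idx).ravel()
    r_eq = np.sqrt(nf / np.pi)
    amps = np.linspace(0.0, 0.8, 17) * r_eq
    amp_costs = [float(np.mean(photometric(mode * a)[0][idx] ** 2)) for a in amps]
    z = mode * amps[int(np.argmin(amp_costs))]

    lam, mu = smoothness, 1e-3
    for _ in range(n_iter):
        r, p, q, s, R = photometric(z)
        B = Lm @ z
        Bc = B - B.mean()
        c0 = 0.5 * float(r @ r) + 0.5 * lam * float(Bc @ Bc)
        dRdp = -L[0] / s - R * p / (s * s)
        dRdq = -L[1] / s - R * q / (s * s)
        J = (sparse.diags(dRdp) @ Dx + sparse.diags(dRdq) @ Dy).tocsr()
        Jf = J[:, idx]
        Lmf = Lm[:, idx]

        def matvec(dzf):
            w = Lmf @ dzf
            w = w - w.mean()
            return Jf.T @ (Jf @ dzf) + lam * (Lmf.T @ w) + mu * dzf

        A = splinalg.LinearOperator((nf, nf), matvec=matvec, dtype=float)
        b = -(Jf.T @ r) - lam * (Lmf.T @ Bc)
        dzf, _ = splinalg.cg(A, b, rtol=1e-5, maxiter=400)
        if not np.all(np.isfinite(dzf)):
            raise ArithmeticError(
                "shape-from-shading update diverged (non-finite step); "
                "increase the smoothness weight"
            )
        dz = np.zeros_like(z)
        dz[idx] = dzf
        step, accepted = 1.0, False
        for _ in range(8):  # backtracking line search
            if cost(z + step * dz, lam) < c0:
                accepted = True
                break
            step *= 0.5
        if accepted:
            z = z + step * dz
            mu = max(mu * 0.7, 1e-4)
        else:
            mu *= 10.0
        lam = max(lam * 0.8, smoothness_floor)

    Z = z.reshape(rows, cols)
    Z = Z - Z[mask].min()
    Z[~mask] = 0.0
    return Z


def _principal_axis_angle(mask: np.ndarray) -> float:
    """Image-moment orientation of the mask's major axis (radians, x-axis=0)."""
    ys, xs = np.nonzero(mask)
    x = xs - xs.mean()
    y = ys - ys.mean()
    cxx, cyy, cxy = (x * x).mean(), (y * y).mean(), (x * y).mean()
    if np.isclose(cxx, cyy) and np.isclose(cxy, 0.0):
        return 0.0  # isotropic (e.g. a disk): default to the image x-axis
    return 0.5 * np.arctan2(2 * cxy, cxx - cyy)


def partition_regions(mask: np.ndarray, n: int = 10) -> RegionSet:
    """Split the mask into ``n`` equal-width bands along its principal axis.

    Band boundaries are equally spaced between the extreme projections of
    mask pixels onto the principal axis; every mask pixel gets a label
    1..n, ordered along the axis.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    angle = _principal_axis_angle(mask)
    ys, xs = np.nonzero(mask)
    proj = xs * np.cos(angle) + ys * np.sin(angle)
    lo, hi = proj.min(), proj.max()
    if hi - lo < n:
        raise ValueError(f"mask spans {hi - lo:.0f} px along its axis; need >= {n}")
    idx = np.minimum((n * (proj - lo) / (hi - lo)).astype(int), n - 1)
    labels = np.zeros(mask.shape, dtype=int)
    labels[ys, xs] = idx + 1
    return RegionSet(labels=labels, n_regions=n, axis_angle_rad=float(angle))


def regional_surface_distance(
    height: np.ndarray,
    region: np.ndarray,
    mm_per_px: float,
    axis_angle_rad: float = 0.0,
) -> float:
    """Mean 3-D transect path length across a region, along the major axis.

    For each pixel row perpendicular to the axis, the in-region pixels are
    ordered along the axis and the polyline length
    ``sum sqrt(dxy^2 + dz^2)`` over adjacent pixels is accumulated; the
    returned distance is the mean over rows.  A flat surface returns the
    region's in-plane width.  Rows with fewer than two pixels are skipped.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("region is empty")
    ys, xs = np.nonzero(region)
    ca, sa = np.cos(axis_angle_rad), np.sin(axis_angle_rad)
    along = xs * ca + ys * sa
    across = -xs * sa + ys * ca
    z = np.asarray(height, dtype=float)[ys, xs]

    lengths = []
    for row in np.unique(np.round(across).astype(int)):
        sel = np.round(across).astype(int) == row
        if sel.sum() < 2:
            continue
        order = np.argsort(along[sel])
        x_mm = along[sel][order] * mm_per_px
        z_mm = z[sel][order]
        lengths.append(float(np.sum(np.hypot(np.diff(x_mm), np.diff(z_mm)))))
    if not lengths:
        raise ValueError("no region row has >= 2 pixels")
    return float(np.mean(lengths))


def regional_strain(
    h_up: np.ndarray,
    h_down: np.ndarray,
    regions: RegionSet,
    mm_per_px: float,
    up_frame: int = -1,
    down_frame: int = -1,
) -> RegionalStrainResult:
    """Per-region strain between the Up and Down surfaces.

    ``strain_r = (S_up_r - S_down_r) / S_down_r`` with both surface
    distances measured on the shared mask and regions.  The two height
    fields must come from identical reconstruction settings so any global
    scale is shared; strain is then comparable across regions.
    """
    if h_up.shape != h_down.shape or h_up.shape != regions.labels.shape:
        raise ValueError("height fields and regions must share one grid")
    n = regions.n_regions
    s_up = np.empty(n)
    s_down = np.empty(n)
    for r in range(1, n + 1):
        reg = regions.region_mask(r)
        s_up[r - 1] = regional_surface_distance(
            h_up, reg, mm_per_px, regions.axis_angle_rad
        )
        s_down[r - 1] = regional_surface_distance(
            h_down, reg, mm_per_px, regions.axis_angle_rad
        )
    if np.any(s_down <= 0):
        raise ValueError("zero reference surface distance in some region")
    return RegionalStrainResult(
        s_up=s_up,
        s_down=s_down,
        strain=(s_up - s_down) / s_down,
        up_frame=up_frame,
        down_frame=down_frame,
    )


def moving_regions(strain: np.ndarray, rel_threshold: float = 0.25) -> np.ndarray:
    """Boolean mask of the strain-bearing ("moving") regions.

    A region counts as moving when its strain reaches ``rel_threshold`` of
    the maximum regional strain.  For a centrally clamped dome the strong
    transect elongation sits in the outer bands; for an asymmetric tissue
    the same rule picks out whichever side beats.
    """
    strain = np.asarray(strain, dtype=float)
    if strain.size == 0:
        raise ValueError("no regions given")
    return strain >= rel_threshold * strain.max()


def compare_stim(
    strains_stim: np.ndarray, strains_nostim: np.ndarray
) -> StimComparison:
    """Region-wise paired contrast of stimulated vs unstimulated strain.

    Inputs are (n_slices, n_regions) arrays of per-slice regional strains.
    Reports the percent difference of region means,
    ``100 (mean_stim - mean_nostim) / mean_nostim``, and a paired
    two-tailed t-test across slices per region (NaN with a single pair).
    """
    a = np.atleast_2d(np.asarray(strains_stim, dtype=float))
    b = np.atleast_2d(np.asarray(strains_nostim, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"paired inputs differ in shape: {a.shape} vs {b.shape}")
    mean_s, mean_n = a.mean(axis=0), b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (mean_s - mean_n) / mean_n
    if a.shape[0] >= 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_rel(a, b, axis=0)
        # zero-variance zero-mean differences: no effect, not undefined
        d = a - b
        degenerate = (d.std(axis=0) == 0) & (d.mean(axis=0) == 0)
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    else:
        t = np.full(a.shape[1], np.nan)
        p = np.full(a.shape[1], np.nan)
    return StimComparison(
        percent_difference=pct, t_statistic=np.asarray(t), p_value=np.asarray(p),
        n_pairs=a.shape[0],
    )


def analyze_strain_pair(
    clip: VideoClip,
    light_direction,
    mask: np.ndarray | None = None,
    n_regions: int = 10,
    n_iter: int = 60,
    albedo_from_down: bool = True,
    ensemble_average: bool = True,
    trace_kwargs: dict | None = None,
) -> RegionalStrainResult:
    """Full single-recording strain pipeline.

    Movement trace (auto-segmented mask unless given) -> peak analysis ->
    Up/Down frame selection -> shape-from-shading of both frames -> ten
    principal-axis bands -> per-region strain.  When ``albedo_from_down``
    is set, the Down frame (membrane near rest, so nearly flat) is used as
    a reflectance reference: both frames are divided by the implied albedo
    before reconstruction.  With ``ensemble_average`` (default), the Up and
    Down images are beat averages — means of the frames at every detected
    peak and valley — which suppresses sensor noise by the square root of
    the number of cycles while leaving noiseless input untouched.
    """
    from .motion import analyze_trace, movement_trace

    if mask is None:
        mask = segment_tissue(clip.frames[0])
    raw = movement_trace(clip, mask)
    _, detrended, peaks = analyze_trace(raw, **(trace_kwargs or {}))
    up, down = select_extreme_frames(detrended, peaks)

    if ensemble_average and len(peaks.peak_indices) > 1:
        frame_up = clip.frames[peaks.peak_indices].mean(axis=0)
        frame_down = clip.frames[peaks.valley_indices].mean(axis=0)
    else:
        frame_up = clip.frames[up]
        frame_down = clip.frames[down]

    L = np.asarray(light_direction, dtype=float)
    L = L / np.linalg.norm(L)
    albedo = None
    if albedo_from_down:
        albedo = frame_down / L[2]  # flat-surface reflectance estimate

    z_up = shape_from_shading(frame_up, mask, L, n_iter, albedo=albedo)
    z_down = shape_from_shading(frame_down, mask, L, n_iter, albedo=albedo)
    # heights are in pixel units; convert to the in-plane length unit
    z_up = z_up * clip.mm_per_px
    z_down = z_down * clip.mm_per_px

    regions = partition_regions(mask, n_regions)
    return regional_strain(
        z_up, z_down, regions, clip.mm_per_px, up_frame=up, down_frame=down
    )
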