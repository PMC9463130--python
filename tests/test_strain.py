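"""Strain pipeline: segmentation, shape-from-shading, regions, strain."""

import numpy as np
import pytest

from ctcm.device_cycle import cap_from_height, height_for_stretch
from ctcm.motion import MotionTrace, detect_peaks_valleys
from ctcm.strain import (
    compare_stim,
    partition_regions,
    regional_strain,
    regional_surface_distance,
    segment_tissue,
    select_extreme_frames,
    shape_from_shading,
)
from ctcm.synthetic import (
    SceneParams,
    lambertian_render,
    make_albedo,
    render_height_field,
    ring_mask,
    simulate_recording,
)


@pytest.fixture(scope="module")
def cap_scene():
    return SceneParams(image_size_px=(128, 128), mm_per_px=8.0 / 128.0)


@pytest.fixture(scope="module")
def cap25(cap_scene):
    """Noiseless Lambertian render of the 25%-stretch cap, uniform albedo."""
    z = render_height_field(cap_from_height(3.5, height_for_stretch(25.0)), cap_scene)
    frame = lambertian_render(z, cap_scene, 1.0)
    return z, frame, ring_mask(cap_scene)


class TestSegmentation:
    def test_bright_disk_iou(self, cap_scene):
        albedo = make_albedo(cap_scene)
        frame = lambertian_render(np.zeros(cap_scene.image_size_px), cap_scene, albedo)
        mask = segment_tissue(frame)
        truth = ring_mask(cap_scene)
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.95

    def test_uniform_frame_rejected(self):
        with pytest.raises(ValueError):
            segment_tissue(np.full((64, 64), 0.5))

    def test_intensity_offset_invariance(self, cap_scene):
        albedo = make_albedo(cap_scene)
        frame = lambertian_render(np.zeros(cap_scene.image_size_px), cap_scene, albedo)
        shifted = np.clip(frame + 0.05, 0, 1)
        m1, m2 = segment_tissue(frame), segment_tissue(shifted)
        assert (m1 ^ m2).sum() / m1.sum() < 0.01


class TestExtremeFrames:
    def test_sinusoid_up_down(self):
        t = np.arange(0, 10, 1 / 30)
        trace = MotionTrace(np.sin(2 * np.pi * 1.2 * t), 30.0)
        ps = detect_peaks_valleys(trace)
        up, down = select_extreme_frames(trace, ps)
        assert trace.value[up] == pytest.approx(1.0, abs=0.01)
        assert trace.value[down] == pytest.approx(-1.0, abs=0.01)

    def test_synthetic_recording_up_frame(self, cycle, scene64):
        from ctcm.motion import analyze_trace, movement_trace

        clip, gt = simulate_recording(cycle, scene64, seed=0, duration_s=5.0)
        mask = ring_mask(scene64)
        _, det, ps = analyze_trace(movement_trace(clip, mask))
        up, down = select_extreme_frames(det, ps)
        true_up_frames = np.flatnonzero(
            gt.apex_height_trace == gt.apex_height_trace.max()
        )
        assert np.min(np.abs(true_up_frames - up)) <= 1
        assert gt.apex_height_trace[down] <= gt.apex_height_trace.min() + 0.05

    def test_monotone_trace_rejected(self):
        trace = MotionTrace(np.linspace(0, 1, 300), 30.0)
        ps = detect_peaks_valleys(trace)
        with pytest.raises(ValueError):
            select_extreme_frames(trace, ps)


class TestShapeFromShading:
    def test_uniform_frame_recovers_flat_surface(self, cap_scene):
        mask = ring_mask(cap_scene)
        L = cap_scene.light
        frame = np.full(cap_scene.image_size_px, L[2])
        z = shape_from_shading(frame, mask, L, n_iter=30)
        assert np.ptp(z[mask]) < 1e-6

    def test_cap_height_recovery(self, cap25, cap_scene):
        z_true, frame, mask = cap25
        z = shape_from_shading(frame, mask, cap_scene.light, n_iter=60)
        zt_px = z_true / cap_scene.mm_per_px
        r = np.corrcoef(z[mask], zt_px[mask])[0, 1]
        assert r >= 0.95

    def test_cap_transect_unimodal(self, cap25, cap_scene):
        _, frame, mask = cap25
        z = shape_from_shading(frame, mask, cap_scene.light, n_iter=60)
        row = z[64][mask[64]]
        peak = int(np.argmax(row))
        assert 0 < peak < len(row) - 1
        tol = 0.02 * np.ptp(row)  # allow sub-pixel ripple
        assert np.all(np.diff(row[: peak + 1]) > -tol)
        assert np.all(np.diff(row[peak:]) < tol)

    def test_deterministic(self, cap25, cap_scene):
        _, frame, mask = cap25
        z1 = shape_from_shading(frame, mask, cap_scene.light, n_iter=15)
        z2 = shape_from_shading(frame, mask, cap_scene.light, n_iter=15)
        assert np.array_equal(z1, z2)


class TestPartition:
    def test_rectangle_equal_bands(self):
        mask = np.zeros((20, 100), bool)
        mask[5:15, :] = True
        regions = partition_regions(mask, 10)
        areas = [regions.region_mask(r).sum() for r in range(1, 11)]
        assert areas == [100] * 10

    def test_disk_symmetry(self, cap_scene):
        mask = ring_mask(cap_scene)
        regions = partition_regions(mask, 10)
        areas = np.array([regions.region_mask(r).sum() for r in range(1, 11)])
        assert np.array_equal(areas, areas[::-1])

    def test_partition_tiles_mask_exactly(self, cap_scene):
        mask = ring_mask(cap_scene)
        regions = partition_regions(mask, 10)
        assert np.array_equal(regions.labels > 0, mask)
        assert np.all(np.unique(regions.labels[mask]) == np.arange(1, 11))

    def test_thin_mask_rejected(self):
        mask = np.zeros((10, 10), bool)
        mask[5, 2:7] = True
        with pytest.raises(ValueError):
            partition_regions(mask, 10)


def analytic_row_arc_ratio(cap, y_mm, x_half_mm):
    """Arc/chord ratio of the sphere's cross-section at offset y."""
    R_y = np.sqrt(cap.sphere_radius_mm**2 - y_mm**2)
    phi = np.arcsin(min(1.0, x_half_mm / R_y))
    return (R_y * phi) / x_half_mm


class TestSurfaceDistance:
    def test_flat_region_returns_width(self):
        mask = np.zeros((20, 50), bool)
        mask[8:12, 10:40] = True
        w = regional_surface_distance(np.zeros((20, 50)), mask, mm_per_px=0.1)
        assert w == pytest.approx(29 * 0.1)

    def test_cap_transect_matches_analytic_arc(self):
        # >= 200 px across the aperture
        scene = SceneParams(image_size_px=(256, 256), mm_per_px=7.2 / 256.0)
        cap = cap_from_height(3.5, 2.2)
        z = render_height_field(cap, scene)
        mask = ring_mask(scene)
        # central band only: rows near the apex, full-width transects
        band = mask.copy()
        band[: 126, :] = False
        band[131:, :] = False
        measured = regional_surface_distance(z, band, scene.mm_per_px)
        # oracle: mean over the same rows of the analytic arc length
        c = (256 - 1) / 2.0
        rows = [r for r in range(126, 131) if band[r].any()]
        oracle = []
        for r in rows:
            y = (r - c) * scene.mm_per_px
            cols = np.flatnonzero(band[r])
            x_half = (cols[-1] - cols[0]) / 2.0 * scene.mm_per_px
            chord = (cols[-1] - cols[0]) * scene.mm_per_px
            oracle.append(chord * analytic_row_arc_ratio(cap, y, x_half))
        assert measured == pytest.approx(np.mean(oracle), rel=0.01)

    def test_resolution_refinement_converges(self):
        vals = []
        for n in (128, 256):
            scene = SceneParams(image_size_px=(n, n), mm_per_px=7.2 / n)
            z = render_height_field(cap_from_height(3.5, 2.2), scene)
            mask = ring_mask(scene)
            vals.append(regional_surface_distance(z, mask, scene.mm_per_px))
        assert vals[1] == pytest.approx(vals[0], rel=0.01)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            regional_surface_distance(np.zeros((10, 10)), np.zeros((10, 10), bool), 0.1)


class TestRegionalStrain:
    def test_identical_fields_zero_strain(self, cap_scene):
        mask = ring_mask(cap_scene)
        regions = partition_regions(mask, 10)
        z = render_height_field(cap_from_height(3.5, 2.0), cap_scene)
        res = regional_strain(z, z, regions, cap_scene.mm_per_px)
        assert np.all(res.strain == 0)

    def test_strain_formula(self, cap_scene):
        mask = ring_mask(cap_scene)
        regions = partition_regions(mask, 10)
        z_up = render_height_field(
            cap_from_height(3.5, height_for_stretch(25.0)), cap_scene
        )
        res = regional_strain(
            z_up, np.zeros_like(z_up), regions, cap_scene.mm_per_px
        )
        assert np.allclose(res.strain, (res.s_up - res.s_down) / res.s_down)
        assert np.all(res.s_down > 0)
        assert np.all(res.strain > 0)

    def test_whole_mask_strain_matches_row_oracle(self, cap_scene):
        """Single-region strain of the 25% cap equals the analytic row-mean."""
        mask = ring_mask(cap_scene)
        regions = partition_regions(mask, 1)
        cap = cap_from_height(3.5, height_for_stretch(25.0))
        z_up = render_height_field(cap, cap_scene)
        res = regional_strain(z_up, np.zeros_like(z_up), regions, cap_scene.mm_per_px)
        # oracle: mean analytic arc length over mean chord length (the
        # region distance is a mean of row lengths, not of row ratios)
        c = (128 - 1) / 2.0
        arcs, chords = [], []
        for r in range(128):
            cols = np.flatnonzero(mask[r])
            if len(cols) < 2:
                continue
            y = (r - c) * cap_scene.mm_per_px
            chord = (cols[-1] - cols[0]) * cap_scene.mm_per_px
            arcs.append(chord * analytic_row_arc_ratio(cap, y, chord / 2.0))
            chords.append(chord)
        oracle = np.mean(arcs) / np.mean(chords) - 1.0
        assert res.strain[0] == pytest.approx(oracle, abs=0.005)
        # the central transect itself carries the full 25% elongation
        central = analytic_row_arc_ratio(cap, 0.0, 3.5) - 1.0
        assert central == pytest.approx(0.25, abs=0.001)


class TestCompareStim:
    def test_identical_groups(self):
        strains = np.array([[0.1, 0.2, 0.3], [0.15, 0.25, 0.35]])
        cmp = compare_stim(strains, strains.copy())
        assert np.allclose(cmp.percent_difference, 0.0)
        assert np.allclose(cmp.t_statistic, 0.0)
        assert np.allclose(cmp.p_value, 1.0)

    def test_antisymmetry(self, rng):
        a = 0.2 + 0.05 * rng.random((4, 10))
        b = 0.2 + 0.05 * rng.random((4, 10))
        fwd = compare_stim(a, b)
        rev = compare_stim(b, a)
        assert np.all(np.sign(fwd.t_statistic) == -np.sign(rev.t_statistic))
        assert np.allclose(fwd.p_value, rev.p_value)

    def test_known_ratio(self):
        base = np.array([[0.10, 0.20, 0.30]])
        cmp = compare_stim(1.2 * base, base)
        assert np.allclose(cmp.percent_difference, 20.0)

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            compare_stim(np.zeros((3, 10)), np.zeros((2, 10)))
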