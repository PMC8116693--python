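"""Threshold → label → 3D-cluster lung segmentation on analytic phantoms."""

import math

import numpy as np
import pytest

from lungvar.phantom import (
    GeometryError,
    GridSpec,
    PhantomGeometry,
    rasterize,
    render_phantom,
)
from lungvar.segmentation import (
    DegeneratePlaneError,
    LungMask,
    SegmentationError,
    VoxelGrid,
    adaptive_threshold_plane,
    cluster_3d,
    compute_volume,
    fractional_volume_series,
    label_and_filter,
    segment_lungs,
)

# Coarse grid for fast tests: same physical extent as the default
# 512 x 512 x 100 acquisition at ~3x coarser in-plane sampling.
FAST_GRID = GridSpec(shape=(192, 192, 100), spacing=(2.031, 2.031, 2.2))


class TestAdaptiveThreshold:
    def test_threshold_between_two_modes(self, rng):
        plane = np.where(rng.random((64, 64)) < 0.4, 10.0, 200.0)
        threshold, binary = adaptive_threshold_plane(plane)
        assert 10.0 < threshold < 200.0
        assert binary.sum() == (plane == 10.0).sum()  # air = below threshold

    def test_constant_plane_degenerate(self):
        with pytest.raises(DegeneratePlaneError):
            adaptive_threshold_plane(np.full((32, 32), 7.0))

    def test_empty_plane_rejected(self):
        with pytest.raises(ValueError):
            adaptive_threshold_plane(np.empty((0, 0)))

    def test_phantom_midlung_plane_area(self):
        """Foreground area of the central coronal-stack plane matches the
        analytic two-ellipse cross-section within 3 %."""
        volume, truth = render_phantom(None, 5.0, grid=FAST_GRID)
        k = FAST_GRID.shape[2] // 2
        plane = volume.data[:, :, k]
        _, binary = adaptive_threshold_plane(plane)
        filtered, _ = label_and_filter(binary[:, :, None], min_area=20, slice_axis=2)
        area = filtered.sum() * FAST_GRID.spacing[0] * FAST_GRID.spacing[1]
        ap = (k - (FAST_GRID.shape[2] - 1) / 2.0) * FAST_GRID.spacing[2]
        expected = 0.0
        for center, semi in zip(
            truth.geometry.lung_centers, truth.geometry.lung_semi_axes
        ):
            frac = 1.0 - ((ap - center[2]) / semi[2]) ** 2
            expected += math.pi * semi[0] * semi[1] * frac
        # blobs cut by this plane reduce the air cross-section slightly
        assert area == pytest.approx(expected, rel=0.03)


class TestLabelAndFilter:
    def test_two_disjoint_squares(self):
        plane = np.zeros((40, 40, 1), dtype=bool)
        plane[5:15, 5:15, 0] = True
        plane[25:35, 20:35, 0] = True
        filtered, props = label_and_filter(plane, min_area=10)
        assert len(props) == 2
        assert sorted(p["area"] for p in props) == [100, 150]
        assert filtered.sum() == 250

    def test_border_touching_removed(self):
        plane = np.zeros((40, 40, 1), dtype=bool)
        plane[0:10, 5:15, 0] = True  # touches border
        plane[20:30, 20:30, 0] = True
        filtered, props = label_and_filter(plane, min_area=10)
        assert len(props) == 1
        assert filtered[0:10, 5:15, 0].sum() == 0

    def test_small_components_removed(self):
        plane = np.zeros((40, 40, 1), dtype=bool)
        plane[20:22, 20:22, 0] = True  # 4 px
        filtered, props = label_and_filter(plane, min_area=50)
        assert not props and filtered.sum() == 0

    def test_phantom_plane_keeps_two_lungs_only(self):
        volume, _ = render_phantom(None, 5.0, grid=FAST_GRID)
        k = FAST_GRID.shape[2] // 2
        _, binary = adaptive_threshold_plane(volume.data[:, :, k])
        _, props = label_and_filter(binary[:, :, None], min_area=50)
        assert len(props) == 2


class TestCluster3D:
    def test_two_disjoint_masks_counted(self):
        mask = np.zeros((40, 40, 40), dtype=bool)
        mask[5:15, 5:15, 5:15] = True
        mask[25:35, 25:35, 25:35] = True
        lung = cluster_3d(mask, (1.0, 1.0, 1.0))
        assert len(lung.kept_labels) == 2
        assert lung.voxel_count == 2 * 1000

    def test_speck_discarded(self):
        mask = np.zeros((40, 40, 40), dtype=bool)
        mask[5:15, 5:15, 5:15] = True
        mask[30, 30, 30] = True  # isolated speck
        lung = cluster_3d(mask, (1.0, 1.0, 1.0), min_cluster_voxels=100)
        assert lung.voxel_count == 1000

    def test_empty_mask_fails(self):
        with pytest.raises(SegmentationError):
            cluster_3d(np.zeros((10, 10, 10), dtype=bool), (1.0, 1.0, 1.0))

    def test_keep_largest_limits_clusters(self):
        mask = np.zeros((60, 20, 20), dtype=bool)
        mask[0:10, 5:15, 5:15] = True
        mask[20:32, 5:15, 5:15] = True
        mask[40:55, 5:15, 5:15] = True
        lung = cluster_3d(mask, (1.0, 1.0, 1.0), keep_largest=2)
        assert len(lung.kept_labels) == 2
        assert lung.voxel_count == (12 + 15) * 100


class TestComputeVolume:
    def test_million_unit_voxels_is_one_litre(self):
        mask = LungMask(
            mask=np.ones((100, 100, 100), dtype=bool),
            labels=np.ones((100, 100, 100), dtype=int),
            kept_labels=(1,),
            spacing=(1.0, 1.0, 1.0),
        )
        assert compute_volume(mask) == pytest.approx(1.000)

    def test_single_voxel_at_acquisition_spacing(self):
        mask = LungMask(
            mask=np.ones((1, 1, 1), dtype=bool),
            labels=np.ones((1, 1, 1), dtype=int),
            kept_labels=(1,),
            spacing=(0.7617, 0.7617, 2.2),
        )
        assert compute_volume(mask) == pytest.approx(1.27647e-6, rel=1e-4)

    def test_spacing_equivariance(self):
        mask = LungMask(
            mask=np.ones((10, 10, 10), dtype=bool),
            labels=np.ones((10, 10, 10), dtype=int),
            kept_labels=(1,),
            spacing=(1.0, 1.0, 1.0),
        )
        v1 = compute_volume(mask)
        v2 = compute_volume(mask, spacing=(2.0, 2.0, 2.0))
        assert v2 == pytest.approx(8.0 * v1)


class TestFractionalVolumeSeries:
    def test_direct_division(self):
        np.testing.assert_allclose(
            fractional_volume_series([6.0, 5.7, 5.4]), [1.0, 0.95, 0.90]
        )

    def test_single_acquisition(self):
        np.testing.assert_allclose(fractional_volume_series([4.2]), [1.0])

    def test_nonpositive_initial_rejected(self):
        with pytest.raises(ValueError):
            fractional_volume_series([0.0, 1.0])


class TestSegmentLungs:
    def test_fast_phantom_volume_within_two_percent(self):
        volume, truth = render_phantom(None, 5.0, grid=FAST_GRID, noise_sd=3.0, rng=1)
        _, report = segment_lungs(volume)
        assert report["n_clusters_kept"] == 2
        assert report["volume_l"] == pytest.approx(truth.analytic_volume_l, rel=0.02)

    def test_monotone_in_phantom_size(self):
        estimates = []
        for target in (3.5, 5.0, 6.5):
            volume, _ = render_phantom(None, target, grid=FAST_GRID)
            _, report = segment_lungs(volume)
            estimates.append(report["volume_l"])
        assert estimates[0] < estimates[1] < estimates[2]

    def test_idempotent_on_binary_mask(self):
        volume, _ = render_phantom(None, 4.0, grid=FAST_GRID)
        mask, _ = segment_lungs(volume)
        binary_grid = VoxelGrid(
            np.where(mask.mask, 0.0, 1.0), FAST_GRID.spacing, axes=FAST_GRID.axes
        )
        mask2, _ = segment_lungs(binary_grid)
        np.testing.assert_array_equal(mask2.mask, mask.mask)

    def test_nifti_roundtrip(self, tmp_path):
        volume, _ = render_phantom(None, 4.0, grid=FAST_GRID)
        path = tmp_path / "phantom.nii"
        volume.to_nifti(path)
        loaded = VoxelGrid.from_nifti(path)
        assert loaded.axes == volume.axes
        np.testing.assert_allclose(loaded.spacing, volume.spacing, rtol=1e-6)
        _, report = segment_lungs(loaded)
        _, report0 = segment_lungs(volume)
        assert report["volume_l"] == pytest.approx(report0["volume_l"], rel=1e-6)


class TestPhantomGeometry:
    def test_analytic_volume_matches_target(self):
        _, truth = render_phantom(None, 5.0)
        assert 4.95 <= truth.analytic_volume_l <= 5.05
        assert truth.analytic_volume_l == pytest.approx(5.0, rel=1e-9)

    def test_doubling_semi_axes_scales_volume_eightfold(self):
        _, truth = render_phantom(None, 4.0, blob_radius=0.0)
        g = truth.geometry
        doubled = PhantomGeometry(
            lung_centers=g.lung_centers,
            lung_semi_axes=2.0 * g.lung_semi_axes,
            body_semi_axes=g.body_semi_axes,
            blob_centers=g.blob_centers,
            blob_radius=0.0,
        )
        assert doubled.ellipsoid_volume_mm3 == pytest.approx(
            8.0 * g.ellipsoid_volume_mm3
        )

    def test_zero_blob_radius_pure_ellipsoids(self):
        _, truth = render_phantom(None, 4.0, blob_radius=0.0)
        assert truth.geometry.blob_volume_mm3 == 0.0
        assert truth.geometry.analytic_lung_volume_mm3 == pytest.approx(
            truth.geometry.ellipsoid_volume_mm3
        )

    def test_oversized_target_raises_geometry_error(self):
        with pytest.raises(GeometryError):
            render_phantom(None, 14.0)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            render_phantom(None, 0.0)

    def test_voxelization_error_shrinks_with_spacing(self):
        """Voxelized air volume converges to the analytic ellipsoid volume:
        relative error at half spacing is below the full-spacing error."""
        errors = {}
        for factor in (1.0, 0.5):
            spacing = (4.0 * factor, 4.0 * factor, 4.4 * factor)
            shape = tuple(int(round(e / s)) for e, s in
                          zip((390.0, 390.0, 220.0), spacing))
            grid = GridSpec(shape=shape, spacing=spacing)
            volume, truth = render_phantom(None, 5.0, grid=grid, blob_radius=0.0)
            voxelized = (
                (volume.data == 25.0).sum() * np.prod(spacing) / 1e6
            )
            errors[factor] = abs(voxelized - truth.analytic_volume_l) / truth.analytic_volume_l
        assert errors[0.5] < errors[1.0]

    def test_ground_truth_sidecar(self, tmp_path):
        import json

        volume, truth = render_phantom(None, 4.5, grid=FAST_GRID)
        truth.to_json(tmp_path / "truth.json")
        payload = json.loads((tmp_path / "truth.json").read_text())
        assert payload["analytic_volume_l"] == pytest.approx(4.5)
        assert len(payload["lung_semi_axes_mm"]) == 2
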