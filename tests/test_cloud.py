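"""Disparity reprojection, cloud cleaning, landmark picking, measurement."""

import numpy as np
import pytest

from stereonav.camera import assemble_q, project_point
from stereonav.cloud import (
    PointCloud,
    cloud_from_disparity,
    measure_distance,
    median_absolute_error,
    pick_landmark_3d,
    remove_outliers,
    reproject_pixel,
)
from stereonav.errors import (
    DimensionMismatchError,
    NoDepthAtLandmarkError,
    PointAtInfinityError,
)
from stereonav.stereo import DisparityMap


def _toy_cloud(disp: np.ndarray, q=None):
    """Organized cloud from a disparity array (NaN marks invalid)."""
    q = q if q is not None else assemble_q(1.0, 0.0, 0.0, 0.0, -1.0)
    dmap = DisparityMap(disp.astype(np.float32), np.isfinite(disp))
    img = np.zeros(disp.shape + (3,), dtype=np.uint8)
    return cloud_from_disparity(dmap, q, img)


class TestReprojectPixel:
    def test_unit_rig_hand_value(self, toy_q):
        # Q (1,0,1): X = 1, Y = 0, Z = f = 1, W = -d/tx = 1
        assert np.allclose(reproject_pixel(toy_q, 1.0, 0.0, 1.0), [1.0, 0.0, 1.0])

    def test_principal_point_on_optical_axis(self):
        q = assemble_q(1432.8, 988.53, 546.98, 988.53, -6.09533)
        for d in (5.0, 20.0, 60.0):
            x, y, z = reproject_pixel(q, 988.53, 546.98, d)
            assert x == pytest.approx(0.0, abs=1e-9)
            assert y == pytest.approx(0.0, abs=1e-9)
            assert z > 0

    def test_zero_disparity_rejected(self, toy_q):
        with pytest.raises(PointAtInfinityError):
            reproject_pixel(toy_q, 1.0, 1.0, 0.0)

    def test_depth_monotone_in_disparity(self, toy_q):
        zs = [reproject_pixel(toy_q, 0, 0, d)[2] for d in (0.5, 1.0, 2.0, 8.0)]
        assert all(a > b for a, b in zip(zs, zs[1:]))


class TestCloudFromDisparity:
    def test_all_invalid_gives_empty_cloud(self, toy_q):
        cloud = _toy_cloud(np.full((4, 6), np.nan))
        assert len(cloud) == 0

    def test_constant_disparity_plane(self):
        # toy rig: Z = f/(d * (-1/tx)) = 1/d
        d0 = 0.25
        cloud = _toy_cloud(np.full((5, 7), d0))
        assert len(cloud) == 35
        assert np.allclose(cloud.points[:, 2], 1.0 / d0)

    def test_point_count_equals_valid_pixels(self, default_disparity, default_scene):
        cloud = cloud_from_disparity(
            default_disparity, default_scene.rig.q_matrix, default_scene.frame.left_image
        )
        # zero-disparity pixels reproject to infinity and carry no point
        finite = default_disparity.valid_mask & (default_disparity.disparity != 0)
        assert len(cloud) == int(finite.sum())
        assert cloud.organized

    def test_provenance_roundtrip(self, default_scene):
        """Projecting each point through the left camera returns its pixel."""
        scene = default_scene
        cloud = cloud_from_disparity(
            scene.true_disparity, scene.rig.q_matrix, scene.frame.left_image
        )
        intr = scene.rig.rectified_left_intrinsics()
        px = project_point(intr, cloud.points)
        assert np.max(np.abs(px - cloud.pixel_provenance)) < 1e-6

    def test_colors_sampled_from_left_image(self, toy_q):
        disp = np.full((3, 3), 1.0)
        disp[0, 0] = np.nan
        img = np.arange(27, dtype=np.uint8).reshape(3, 3, 3)
        dmap = DisparityMap(disp.astype(np.float32), np.isfinite(disp))
        cloud = cloud_from_disparity(dmap, toy_q, img)
        i = np.nonzero((cloud.pixel_provenance == [2, 1]).all(axis=1))[0][0]
        assert np.array_equal(cloud.colors[i], img[1, 2])

    def test_dimension_mismatch_rejected(self, toy_q):
        dmap = DisparityMap(np.ones((4, 4), dtype=np.float32), np.ones((4, 4), dtype=bool))
        with pytest.raises(DimensionMismatchError):
            cloud_from_disparity(dmap, toy_q, np.zeros((5, 5, 3), dtype=np.uint8))

    def test_reconstructed_plane_accuracy(self, default_scene):
        """True-disparity reprojection reproduces the rendered surface depth."""
        scene = default_scene
        cloud = cloud_from_disparity(
            scene.true_disparity, scene.rig.q_matrix, scene.frame.left_image
        )
        xs, ys = cloud.pixel_provenance[:, 0], cloud.pixel_provenance[:, 1]
        # limited only by float32 disparity storage
        assert np.max(np.abs(cloud.points[:, 2] - scene.true_depth[ys, xs])) < 1e-4


class TestRemoveOutliers:
    def test_single_far_point_removed(self):
        gx, gy = np.meshgrid(np.arange(10.0), np.arange(10.0))
        grid = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(100)])
        pts = np.vstack([grid, [[100.0, 100.0, 0.0]]])
        cloud = PointCloud(pts)
        out = remove_outliers(cloud, k=8, std_ratio=2.0)
        assert len(out) == 100
        assert np.abs(out.points).max() <= 9.0

        # brute-force oracle: recompute mean k-NN distances directly
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        knn = np.sort(d, axis=1)[:, 1:9].mean(axis=1)
        keep = knn <= knn.mean() + 2.0 * knn.std()
        assert np.array_equal(np.sort(out.points[:, 0]), np.sort(pts[keep][:, 0]))

    def test_never_grows_and_reaches_fixed_point(self):
        """Repeated application monotonically shrinks the cloud and
        stabilizes; on a regular grid the clean points are untouched."""
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 50, (200, 3))
        cloud = PointCloud(pts)
        sizes = [len(cloud)]
        for _ in range(6):
            cloud = remove_outliers(cloud, k=8, std_ratio=3.0)
            sizes.append(len(cloud))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] == sizes[-2]  # fixed point reached

        gx, gy = np.meshgrid(np.arange(8.0), np.arange(8.0))
        grid = PointCloud(np.column_stack([gx.ravel(), gy.ravel(), np.zeros(64)]))
        assert len(remove_outliers(grid, k=8, std_ratio=3.0)) == 64

    def test_empty_cloud_passthrough(self):
        cloud = PointCloud(np.zeros((0, 3)))
        assert len(remove_outliers(cloud)) == 0


class TestPickLandmark:
    def test_window_one_equals_reproject(self, toy_q):
        disp = np.full((5, 5), 2.0)
        cloud = _toy_cloud(disp)
        p = pick_landmark_3d(cloud, (3, 2), window=1)
        assert np.allclose(p, reproject_pixel(toy_q, 3.0, 2.0, 2.0))

    def test_median_over_window(self, toy_q):
        disp = np.full((3, 3), np.nan)
        disp.ravel()[:5] = [7.0, 8.0, 8.0, 8.0, 9.0]
        cloud = _toy_cloud(disp)
        p = pick_landmark_3d(cloud, (1, 1), window=3)
        assert np.allclose(p, reproject_pixel(toy_q, 1.0, 1.0, 8.0))

    def test_gap_raises_documented_error(self, toy_q):
        disp = np.full((9, 9), 1.0)
        disp[2:7, 2:7] = np.nan  # occlusion gap
        cloud = _toy_cloud(disp)
        with pytest.raises(NoDepthAtLandmarkError):
            pick_landmark_3d(cloud, (4, 4), window=3)

    def test_even_window_rejected(self, toy_q):
        cloud = _toy_cloud(np.full((3, 3), 1.0))
        with pytest.raises(ValueError):
            pick_landmark_3d(cloud, (1, 1), window=4)


class TestMeasurement:
    def test_same_pixel_zero(self, toy_q):
        cloud = _toy_cloud(np.full((5, 5), 1.0))
        assert measure_distance(cloud, (2, 2), (2, 2), window=1) == 0.0

    def test_hand_distance(self, toy_q):
        # picks at (1,0,1) and (1,4,1) are 4 mm apart
        cloud = _toy_cloud(np.full((6, 6), 1.0))
        assert measure_distance(cloud, (1, 0), (1, 4), window=1) == pytest.approx(4.0)

    def test_median_absolute_error_trivial(self):
        med, (q1, q3) = median_absolute_error([1.0, 2.0], [1.0, 2.0])
        assert med == 0.0 and q1 == 0.0 and q3 == 0.0

    def test_median_absolute_error_hand(self):
        med, iqr = median_absolute_error([1, 2, 3], [1, 1, 1])
        assert med == pytest.approx(1.0)
        assert iqr == (pytest.approx(0.5), pytest.approx(1.5))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            median_absolute_error([1.0], [1.0, 2.0])
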