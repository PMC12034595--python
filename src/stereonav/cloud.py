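"""Metric 3D point clouds from disparity, landmark picking, measurement.

Every valid disparity pixel reprojects through the rig's 4x4 matrix Q to a
3D point in the rectified left-camera frame (+x right, +y down, +z into
the scene, units mm), colored from the left image and tagged with its
source pixel (provenance).  Organized clouds keep the generating image
grid so image clicks can be turned into 3D landmarks, depths can be read
back per pixel, and diameters can be measured directly on the cloud.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    DegenerateReprojectionError,
    DimensionMismatchError,
    NoDepthAtLandmarkError,
    PointAtInfinityError,
)
from .stereo import DisparityMap

__all__ = [
    "PointCloud",
    "reproject_pixel",
    "cloud_from_disparity",
    "remove_outliers",
    "pick_landmark_3d",
    "measure_distance",
    "median_absolute_error",
]


@dataclass
class PointCloud:
    """Colored metric point cloud in the rectified left-camera frame.

    ``pixel_provenance`` stores the source pixel ``(x, y)`` of every
    point.  For organized clouds ``index_map`` maps each valid pixel of
    the generating (H, W) grid to its row in ``points`` (-1 elsewhere),
    and ``point_disparity``/``q`` retain what is needed to reproject
    median-filtered picks.
    """

    points: np.ndarray
    colors: np.ndarray = field(default=None)  # type: ignore[assignment]
    pixel_provenance: np.ndarray = field(default=None)  # type: ignore[assignment]
    index_map: Optional[np.ndarray] = None
    point_disparity: Optional[np.ndarray] = None
    q: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        n = len(self.points)
        if self.colors is None:
            self.colors = np.full((n, 3), 200, dtype=np.uint8)
        self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(n, 3)
        if self.pixel_provenance is None:
            self.pixel_provenance = np.full((n, 2), -1, dtype=np.int64)
        self.pixel_provenance = np.asarray(self.pixel_provenance, dtype=np.int64).reshape(n, 2)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def organized(self) -> bool:
        return self.index_map is not None

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Subset by boolean mask; an organized cloud stays organized."""
        mask = np.asarray(mask, dtype=bool)
        index_map = None
        if self.index_map is not None:
            index_map = np.full_like(self.index_map, -1)
            new_idx = np.cumsum(mask) - 1
            keep = self.index_map >= 0
            old = self.index_map[keep]
            remapped = np.where(mask[old], new_idx[old], -1)
            index_map[keep] = remapped
        return PointCloud(
            self.points[mask],
            self.colors[mask],
            self.pixel_provenance[mask],
            index_map,
            None if self.point_disparity is None else self.point_disparity[mask],
            self.q,
        )


def reproject_pixel(q: np.ndarray, x: float, y: float, d: float) -> np.ndarray:
    """Triangulate one pixel: ``(X,Y,Z,W) = Q (x,y,d,1)``, return X/W, Y/W, Z/W (mm)."""
    q = np.asarray(q, dtype=float)
    if d == 0:
        raise PointAtInfinityError("zero disparity reprojects to infinity")
    vec = q @ np.array([x, y, d, 1.0])
    if vec[3] == 0:
        raise DegenerateReprojectionError("homogeneous W = 0 in reprojection")
    return vec[:3] / vec[3]


def _reproject_grid(q: np.ndarray, xs: np.ndarray, ys: np.ndarray, ds: np.ndarray) -> np.ndarray:
    homo = np.stack([xs, ys, ds, np.ones_like(xs)], axis=-1) @ np.asarray(q, dtype=float).T
    return homo[..., :3] / homo[..., 3:4]


def cloud_from_disparity(dmap: DisparityMap, q: np.ndarray, left_image: np.ndarray) -> PointCloud:
    """Build an organized colored cloud from every valid disparity pixel."""
    h, w = dmap.shape
    left_image = np.asarray(left_image)
    if left_image.shape[:2] != (h, w):
        raise DimensionMismatchError(
            f"image shape {left_image.shape[:2]} does not match disparity shape {(h, w)}"
        )
    valid = dmap.valid_mask & (dmap.disparity != 0) & np.isfinite(dmap.disparity)
    ys, xs = np.nonzero(valid)
    ds = dmap.disparity[ys, xs].astype(float)
    points = _reproject_grid(np.asarray(q, dtype=float), xs.astype(float), ys.astype(float), ds)
    if left_image.ndim == 2:
        colors = np.repeat(left_image[ys, xs][:, None], 3, axis=1)
    else:
        colors = left_image[ys, xs, :3]
    index_map = np.full((h, w), -1, dtype=np.int64)
    index_map[ys, xs] = np.arange(len(xs))
    return PointCloud(
        points=points,
        colors=colors.astype(np.uint8),
        pixel_provenance=np.column_stack([xs, ys]),
        index_map=index_map,
        point_disparity=ds,
        q=np.asarray(q, dtype=float).copy(),
    )


def remove_outliers(cloud: PointCloud, k: int = 8, std_ratio: float = 2.0) -> PointCloud:
    """Statistical outlier removal.

    A point is dropped when its mean distance to its ``k`` nearest
    neighbors exceeds the global mean of that statistic by more than
    ``std_ratio`` standard deviations.  Never increases the point count.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(cloud)
    if n == 0:
        return cloud
    if n <= k:
        return cloud.select(np.ones(n, dtype=bool))
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k + 1)
    mean_knn = dists[:, 1:].mean(axis=1)
    thresh = mean_knn.mean() + std_ratio * mean_knn.std()
    return cloud.select(mean_knn <= thresh)


def pick_landmark_3d(cloud: PointCloud, pixel: tuple[int, int], window: int = 5) -> np.ndarray:
    """Turn an image click into a 3D landmark (mm).

    Takes the median disparity over valid pixels in an odd ``window``
    centered at the clicked pixel and reprojects it at the clicked
    coordinates — robust to single-pixel dropouts in the disparity map.
    Raises :class:`NoDepthAtLandmarkError` when the whole window falls in
    a point-cloud gap (e.g. behind an occluding instrument).
    """
    if not cloud.organized or cloud.point_disparity is None or cloud.q is None:
        raise ValueError("pick_landmark_3d requires an organized cloud built from a disparity map")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    h, w = cloud.index_map.shape
    x, y = int(round(pixel[0])), int(round(pixel[1]))
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"pixel {pixel} outside image {(w, h)}")
    half = window // 2
    patch = cloud.index_map[
        max(0, y - half) : min(h, y + half + 1), max(0, x - half) : min(w, x + half + 1)
    ]
    idx = patch[patch >= 0]
    if idx.size == 0:
        raise NoDepthAtLandmarkError(
            f"no valid depth in a {window}x{window} window at pixel ({x}, {y})"
        )
    d_med = float(np.median(cloud.point_disparity[idx]))
    return reproject_pixel(cloud.q, float(x), float(y), d_med)


def measure_distance(
    cloud: PointCloud, pixel_a: tuple[int, int], pixel_b: tuple[int, int], window: int = 5
) -> float:
    """Euclidean distance (mm) between two picked 3D points."""
    pa = pick_landmark_3d(cloud, pixel_a, window)
    pb = pick_landmark_3d(cloud, pixel_b, window)
    return float(np.linalg.norm(pa - pb))


def median_absolute_error(measured, reference) -> tuple[float, tuple[float, float]]:
    """Median and IQR of ``|measured - reference|`` (mm).

    Quartiles use linear interpolation so results are reproducible
    bit-for-bit across platforms.
    """
    measured = np.asarray(measured, dtype=float).ravel()
    reference = np.asarray(reference, dtype=float).ravel()
    if measured.shape != reference.shape or measured.size == 0:
        raise ValueError("measured and reference must be equal-length non-empty lists")
    err = np.abs(measured - reference)
    q1, q3 = np.percentile(err, [25, 75], method="linear")
    return float(np.median(err)), (float(q1), float(q3))
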