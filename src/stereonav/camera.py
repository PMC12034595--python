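"""Pinhole camera model, lens distortion and the stereo reprojection matrix.

The stereo rig is summarized, after rectification, by the 4x4 reprojection
matrix Q that maps a homogeneous pixel-disparity vector ``(x, y, d, 1)`` to
homogeneous 3D coordinates in the left camera frame::

    Q = [[1, 0,  0,      -c_x1          ],
         [0, 1,  0,      -c_y           ],
         [0, 0,  0,       f             ],
         [0, 0, -1/T_x,  (c_x1-c_x2)/T_x]]

where ``f`` is the rectified focal length in pixels, ``(c_x1, c_y)`` and
``c_x2`` the rectified principal points of the left and right cameras, and
``T_x`` the signed stereo baseline in mm.  With the convention used
throughout this package the right camera sits at ``+x`` in the left camera
frame, ``T_x`` is negative, and disparity ``d = x_left - x_right`` is
positive for points in front of the rig, giving ``Z = f |T_x| / d``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    BehindCameraError,
    ConvergenceError,
    InvalidBaselineError,
    InvalidIntrinsicsError,
)

__all__ = [
    "CameraIntrinsics",
    "StereoRig",
    "CheckerboardSpec",
    "assemble_q",
    "project_point",
    "distort_pixel",
    "undistort_pixel",
    "mean_reprojection_error",
]


@dataclass
class CameraIntrinsics:
    """Pinhole intrinsics with Brown-Conrady distortion.

    Parameters
    ----------
    focal_length_px : float
        Focal length ``f`` in pixels (square pixels assumed).
    principal_point_px : tuple of float
        Principal point ``(c_x, c_y)`` in pixels.
    image_size : tuple of int
        ``(width, height)`` in pixels.
    distortion : array-like of 5 floats
        ``(k1, k2, p1, p2, k3)``: radial k1, k2, k3 and tangential p1, p2.
    """

    focal_length_px: float
    principal_point_px: tuple[float, float]
    image_size: tuple[int, int]
    distortion: np.ndarray = field(default_factory=lambda: np.zeros(5))

    def __post_init__(self) -> None:
        if self.focal_length_px <= 0:
            raise InvalidIntrinsicsError(
                f"focal length must be positive, got {self.focal_length_px}"
            )
        w, h = self.image_size
        if w <= 0 or h <= 0 or int(w) != w or int(h) != h:
            raise InvalidIntrinsicsError(f"image_size must be positive integers, got {self.image_size}")
        self.image_size = (int(w), int(h))
        self.principal_point_px = (float(self.principal_point_px[0]), float(self.principal_point_px[1]))
        cx, cy = self.principal_point_px
        if not (0 <= cx <= w and 0 <= cy <= h):
            warnings.warn(
                f"principal point {self.principal_point_px} lies outside the image "
                f"bounds {self.image_size}; unusual for a real rig",
                stacklevel=2,
            )
        self.distortion = np.asarray(self.distortion, dtype=float).reshape(5).copy()

    @property
    def has_distortion(self) -> bool:
        return bool(np.any(self.distortion != 0))


@dataclass
class CheckerboardSpec:
    """Planar calibration checkerboard.

    ``inner_corner_grid`` counts detectable inner corners ``(n_x, n_y)``.
    A board quoted as "R x C squares" has ``(R-1) x (C-1)`` inner corners;
    use :meth:`from_squares` for that dialect.
    """

    inner_corner_grid: tuple[int, int]
    square_size_mm: float

    def __post_init__(self) -> None:
        nx, ny = self.inner_corner_grid
        if nx < 2 or ny < 2:
            raise ValueError("inner corner grid must be at least 2x2")
        if self.square_size_mm <= 0:
            raise ValueError("square size must be positive")

    @classmethod
    def from_squares(
        cls, rows: int, cols: int, square_size_mm: float, *, counts_inner_corners: bool = False
    ) -> "CheckerboardSpec":
        """Build a spec from a "rows x cols" board description.

        By default ``rows x cols`` counts squares (so a 9x7 board has 8x6
        inner corners); set ``counts_inner_corners=True`` if the description
        already counts corners.
        """
        if counts_inner_corners:
            return cls((rows, cols), square_size_mm)
        return cls((rows - 1, cols - 1), square_size_mm)

    @property
    def corner_count(self) -> int:
        return self.inner_corner_grid[0] * self.inner_corner_grid[1]

    def object_points(self) -> np.ndarray:
        """Inner-corner coordinates (N, 3) in the board frame, mm, z = 0."""
        nx, ny = self.inner_corner_grid
        xs, ys = np.meshgrid(np.arange(nx), np.arange(ny))
        pts = np.column_stack(
            [xs.ravel() * self.square_size_mm, ys.ravel() * self.square_size_mm, np.zeros(nx * ny)]
        )
        # center the board on its own origin so poses are easier to sample
        pts[:, 0] -= (nx - 1) * self.square_size_mm / 2
        pts[:, 1] -= (ny - 1) * self.square_size_mm / 2
        return pts


def assemble_q(f: float, cx1: float, cy: float, cx2: float, tx: float) -> np.ndarray:
    """Assemble the 4x4 stereo reprojection matrix Q.

    Parameters are the rectified intrinsics: focal length ``f`` (px), left
    principal point ``(cx1, cy)`` (px), right principal x ``cx2`` (px) and
    the signed baseline ``tx`` (mm, negative under this package's
    convention so that entry (4,3) = -1/tx is positive).
    """
    if tx == 0:
        raise InvalidBaselineError("baseline T_x must be nonzero")
    if f <= 0:
        raise InvalidIntrinsicsError(f"focal length must be positive, got {f}")
    q = np.zeros((4, 4), dtype=float)
    q[0, 0] = 1.0
    q[0, 3] = -cx1
    q[1, 1] = 1.0
    q[1, 3] = -cy
    q[2, 3] = f
    q[3, 2] = -1.0 / tx
    q[3, 3] = (cx1 - cx2) / tx
    return q


@dataclass
class StereoRig:
    """Calibrated stereo rig.

    The relative pose maps left-frame coordinates to right-frame
    coordinates as ``x_r = R (x_l - t)`` where ``t`` is the right camera
    center expressed in the left camera frame (mm).  For a rectified rig
    ``R = I`` and ``t = (|T_x|, 0, 0)``.

    ``baseline_tx_mm`` is the signed baseline ``T_x``; it is negative for
    the standard right-at-+x layout so that the Q entry ``-1/T_x`` is
    positive (asserted at construction).
    """

    left: CameraIntrinsics
    right: CameraIntrinsics
    rotation: np.ndarray
    translation: np.ndarray
    rectified_focal: float
    rectified_left_principal: tuple[float, float]
    rectified_right_principal_x: float
    baseline_tx_mm: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.baseline_tx_mm == 0:
            raise InvalidBaselineError("baseline T_x must be nonzero")
        if self.rectified_focal <= 0:
            raise InvalidIntrinsicsError("rectified focal length must be positive")

    @property
    def q_matrix(self) -> np.ndarray:
        """Reprojection matrix assembled from the rectified parameters."""
        cx1, cy = self.rectified_left_principal
        return assemble_q(
            self.rectified_focal, cx1, cy, self.rectified_right_principal_x, self.baseline_tx_mm
        )

    @property
    def baseline_mm(self) -> float:
        """Unsigned baseline length |T_x| in mm."""
        return abs(self.baseline_tx_mm)

    def rectified_left_intrinsics(self) -> CameraIntrinsics:
        return CameraIntrinsics(
            self.rectified_focal, self.rectified_left_principal, self.left.image_size
        )

    def rectified_right_intrinsics(self) -> CameraIntrinsics:
        cy = self.rectified_left_principal[1]
        return CameraIntrinsics(
            self.rectified_focal,
            (self.rectified_right_principal_x, cy),
            self.right.image_size,
        )

    @classmethod
    def parallel(
        cls,
        focal_px: float,
        principal_point_px: tuple[float, float],
        image_size: tuple[int, int],
        baseline_mm: float,
    ) -> "StereoRig":
        """Ideal already-rectified rig with identical cameras.

        ``baseline_mm`` is the unsigned camera separation; the stored
        signed ``T_x`` is ``-baseline_mm``.
        """
        if baseline_mm <= 0:
            raise InvalidBaselineError("baseline length must be positive")
        intr = CameraIntrinsics(focal_px, principal_point_px, image_size)
        intr_r = CameraIntrinsics(focal_px, principal_point_px, image_size)
        return cls(
            left=intr,
            right=intr_r,
            rotation=np.eye(3),
            translation=np.array([baseline_mm, 0.0, 0.0]),
            rectified_focal=focal_px,
            rectified_left_principal=principal_point_px,
            rectified_right_principal_x=principal_point_px[0],
            baseline_tx_mm=-baseline_mm,
        )


def _normalize(intr: CameraIntrinsics, pixel: np.ndarray) -> np.ndarray:
    cx, cy = intr.principal_point_px
    return (pixel - np.array([cx, cy])) / intr.focal_length_px


def _denormalize(intr: CameraIntrinsics, xy: np.ndarray) -> np.ndarray:
    cx, cy = intr.principal_point_px
    return xy * intr.focal_length_px + np.array([cx, cy])


def _distort_normalized(dist: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Brown-Conrady forward distortion in normalized image coordinates."""
    k1, k2, p1, p2, k3 = dist
    x, y = xy[..., 0], xy[..., 1]
    r2 = x * x + y * y
    radial = 1 + k1 * r2 + k2 * r2**2 + k3 * r2**3
    xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    return np.stack([xd, yd], axis=-1)


def distort_pixel(intrinsics: CameraIntrinsics, pixel) -> np.ndarray:
    """Apply forward lens distortion to ideal (undistorted) pixel(s)."""
    pixel = np.asarray(pixel, dtype=float)
    if not np.all(np.isfinite(pixel)):
        raise ValueError("pixel coordinates must be finite")
    xy = _normalize(intrinsics, pixel)
    return _denormalize(intrinsics, _distort_normalized(intrinsics.distortion, xy))


def undistort_pixel(
    intrinsics: CameraIntrinsics, pixel, *, max_iter: int = 50, tol: float = 1e-10
) -> np.ndarray:
    """Invert lens distortion by fixed-point iteration.

    Converges to better than 1e-8 normalized units for realistic
    coefficients; raises :class:`ConvergenceError` otherwise.
    """
    pixel = np.asarray(pixel, dtype=float)
    if not np.all(np.isfinite(pixel)):
        raise ValueError("pixel coordinates must be finite")
    xy_d = _normalize(intrinsics, pixel)
    xy = xy_d.copy()
    for _ in range(max_iter):
        delta = _distort_normalized(intrinsics.distortion, xy) - xy
        xy_new = xy_d - delta
        if np.max(np.abs(xy_new - xy)) < tol:
            xy = xy_new
            break
        xy = xy_new
    else:
        err = np.max(np.abs(_distort_normalized(intrinsics.distortion, xy) - xy_d))
        if err > 1e-8:
            raise ConvergenceError(f"undistortion did not converge (residual {err:.2e})")
    return _denormalize(intrinsics, xy)


def project_point(intrinsics: CameraIntrinsics, point) -> np.ndarray:
    """Project camera-frame 3D point(s) (mm) to pixel coordinates.

    Applies the pinhole model ``x = f X/Z + c_x, y = f Y/Z + c_y`` followed
    by forward distortion when coefficients are nonzero.
    """
    point = np.asarray(point, dtype=float)
    z = point[..., 2]
    if np.any(z <= 0):
        raise BehindCameraError("cannot project points with Z <= 0")
    xy = point[..., :2] / z[..., None]
    if intrinsics.has_distortion:
        xy = _distort_normalized(intrinsics.distortion, xy)
    return _denormalize(intrinsics, xy)


def mean_reprojection_error(observed, reprojected, *, statistic: str = "mean") -> float:
    """Mean (or RMS) Euclidean distance between corresponding pixel sets."""
    observed = np.asarray(observed, dtype=float).reshape(-1, 2)
    reprojected = np.asarray(reprojected, dtype=float).reshape(-1, 2)
    if observed.shape != reprojected.shape:
        raise ValueError(
            f"point sets differ in length: {observed.shape[0]} vs {reprojected.shape[0]}"
        )
    if observed.shape[0] == 0:
        raise ValueError("need at least one point pair")
    d = np.linalg.norm(observed - reprojected, axis=1)
    if statistic == "mean":
        return float(np.mean(d))
    if statistic == "rms":
        return float(np.sqrt(np.mean(d * d)))
    raise ValueError(f"unknown statistic {statistic!r} (use 'mean' or 'rms')")
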