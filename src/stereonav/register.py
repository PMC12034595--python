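"""Landmark-based rigid registration (Kabsch/SVD least squares).

The preoperative model (moving) is aligned onto the intraoperative point
cloud (fixed) from ordered pairs of corresponding bifurcation landmarks:
``k_preop`` picked on the CT-derived mesh, ``k_intraop`` picked on the
reconstructed cloud.  The optimal proper rotation and translation minimize
the sum of squared distances; the residual root-mean-squared distance
(RMSD) is the fiducial registration error reported to the user.

Both point sets are metric (mm), so no scale factor is fitted by default;
an expert-mode flag enables Umeyama similarity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateConfigurationError, InsufficientLandmarksError

__all__ = [
    "LandmarkSet",
    "RigidTransform",
    "RegistrationResult",
    "fit_rigid",
    "rmsd",
    "apply_transform",
]

FRAME_PREOP = "preop"
FRAME_INTRAOP = "intraop"


@dataclass
class LandmarkSet:
    """Ordered, named 3D landmarks in mm.

    Order defines correspondence between paired sets; names must be
    unique.  ``frame`` tags whether the points live in the preoperative
    model frame or the intraoperative (left-camera) frame.
    """

    points: np.ndarray
    names: list[str] = field(default_factory=list)
    frame: str = FRAME_INTRAOP

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError("landmark points must be (N, 3)")
        if not self.names:
            self.names = [f"F-{i + 1}" for i in range(len(self.points))]
        if len(self.names) != len(self.points):
            raise ValueError("number of names must match number of points")
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, names: Sequence[str]) -> "LandmarkSet":
        idx = [self.names.index(n) for n in names]
        return LandmarkSet(self.points[idx], [self.names[i] for i in idx], self.frame)


@dataclass
class RigidTransform:
    """Proper rigid motion ``p -> R p + t`` (rotation 3x3, translation mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-10):
            raise ValueError("rotation matrix is not orthonormal (R^T R != I)")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-10):
            raise ValueError("rotation matrix must be proper (det = +1)")

    def apply(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 row-major matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()


@dataclass
class RegistrationResult:
    """Rigid fit plus its fiducial registration error."""

    transform: RigidTransform
    rmsd_mm: float
    residuals_mm: np.ndarray
    n_landmarks: int
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.residuals_mm = np.asarray(self.residuals_mm, dtype=float)
        assert self.rmsd_mm >= 0


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, LandmarkSet):
        return obj.points
    return np.atleast_2d(np.asarray(obj, dtype=float))


def rmsd(a, b) -> float:
    """Root mean squared distance between corresponding points (mm)."""
    pa, pb = _as_points(a), _as_points(b)
    if pa.shape != pb.shape:
        raise ValueError(f"point sets differ in shape: {pa.shape} vs {pb.shape}")
    if len(pa) == 0:
        raise ValueError("need at least one point pair")
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def _check_not_collinear(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = s[0] if s[0] > 0 else 1.0
    if s[1] / scale < 1e-9:
        raise DegenerateConfigurationError(
            "landmarks are collinear; rotation about the line is unconstrained"
        )


def fit_rigid(moving, fixed, *, allow_scale: bool = False) -> RegistrationResult:
    """Least-squares rigid fit of ``moving`` landmarks onto ``fixed``.

    Kabsch/Umeyama procedure: subtract centroids, build the 3x3
    cross-covariance, take its SVD, correct the determinant sign so the
    rotation is proper (no reflection), and recover the translation from
    the centroids.  Residuals and RMSD are evaluated after applying the
    fitted transform to the moving set.

    ``allow_scale=True`` additionally fits a global similarity scale
    (expert mode; both frames are normally metric mm so the default is a
    pure rigid motion).
    """
    p_mov, p_fix = _as_points(moving), _as_points(fixed)
    if p_mov.shape != p_fix.shape:
        raise ValueError(f"landmark sets differ in shape: {p_mov.shape} vs {p_fix.shape}")
    n = len(p_mov)
    if n < 3:
        raise InsufficientLandmarksError(f"rigid fit needs >= 3 landmark pairs, got {n}")
    _check_not_collinear(p_mov)

    mu_mov = p_mov.mean(axis=0)
    mu_fix = p_fix.mean(axis=0)
    a = p_mov - mu_mov
    b = p_fix - mu_fix
    h = a.T @ b / n
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T

    scale = 1.0
    if allow_scale:
        var_mov = np.mean(np.sum(a * a, axis=1))
        scale = float(np.trace(np.diag(s) @ corr) / var_mov)

    t = mu_fix - scale * r @ mu_mov
    transform = RigidTransform(r, t)
    aligned = scale * (p_mov @ r.T) + t
    residuals = np.linalg.norm(aligned - p_fix, axis=1)
    return RegistrationResult(
        transform=transform,
        rmsd_mm=float(np.sqrt(np.mean(residuals**2))),
        residuals_mm=residuals,
        n_landmarks=n,
        scale=scale,
    )


def apply_transform(geometry, t: RigidTransform):
    """Apply a rigid transform to a point cloud, mesh or landmark set.

    Vertices/points map as ``p -> R p + t``; faces, colors, names and all
    other attributes are preserved.  Returns a new object of the same type.
    """
    from dataclasses import replace

    if isinstance(geometry, LandmarkSet):
        return replace(geometry, points=t.apply(geometry.points))
    if hasattr(geometry, "vertices") and hasattr(geometry, "faces"):
        return replace(geometry, vertices=t.apply(geometry.vertices))
    if hasattr(geometry, "points"):
        return replace(geometry, points=t.apply(geometry.points))
    raise TypeError(f"cannot apply transform to {type(geometry).__name__}")
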