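"""Stereo calibration from checkerboard corner observations.

Classical plane-based (Zhang) initialization — per-view homographies,
closed-form intrinsics from the absolute-conic constraints, per-view
extrinsics — followed by a joint nonlinear refinement of both cameras'
intrinsics, distortion, the relative pose and all board poses, minimizing
the total reprojection error with ``scipy.optimize.least_squares``.

Square pixels (one focal length per camera) and zero skew are assumed,
matching the camera model used everywhere else in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .camera import (
    CameraIntrinsics,
    CheckerboardSpec,
    StereoRig,
    _denormalize,
    _distort_normalized,
    mean_reprojection_error,
)
from .errors import CalibrationDegenerateError

__all__ = ["CalibrationResult", "estimate_stereo_calibration"]


@dataclass
class CalibrationResult:
    """Fitted rig plus fit-quality diagnostics."""

    rig: StereoRig
    mean_reprojection_error_px: float
    per_view_errors_px: np.ndarray
    board_poses: list  # (rotvec, t) of the board in the left camera frame


def _homography_dlt(obj_xy: np.ndarray, img_xy: np.ndarray) -> np.ndarray:
    """Normalized DLT homography from board-plane mm to pixels."""

    def normalizer(pts):
        mu = pts.mean(axis=0)
        scale = np.sqrt(2) / max(np.mean(np.linalg.norm(pts - mu, axis=1)), 1e-12)
        t = np.array([[scale, 0, -scale * mu[0]], [0, scale, -scale * mu[1]], [0, 0, 1]])
        return t

    t_obj = normalizer(obj_xy)
    t_img = normalizer(img_xy)
    o = (np.column_stack([obj_xy, np.ones(len(obj_xy))]) @ t_obj.T)[:, :2]
    p = (np.column_stack([img_xy, np.ones(len(img_xy))]) @ t_img.T)[:, :2]
    n = len(o)
    a = np.zeros((2 * n, 9))
    a[0::2, 0:2] = o
    a[0::2, 2] = 1
    a[0::2, 6:8] = -o * p[:, 0:1]
    a[0::2, 8] = -p[:, 0]
    a[1::2, 3:5] = o
    a[1::2, 5] = 1
    a[1::2, 6:8] = -o * p[:, 1:2]
    a[1::2, 8] = -p[:, 1]
    _, _, vt = np.linalg.svd(a)
    h_norm = vt[-1].reshape(3, 3)
    h = np.linalg.inv(t_img) @ h_norm @ t_obj
    return h / h[2, 2]


def _intrinsics_from_homographies(hs: Sequence[np.ndarray], image_size) -> tuple[float, float, float]:
    """Closed-form (f, cx, cy) from the zero-skew absolute-conic constraints."""

    def v(h, i, j):
        return np.array(
            [
                h[0, i] * h[0, j],
                h[1, i] * h[1, j],
                h[2, i] * h[0, j] + h[0, i] * h[2, j],
                h[2, i] * h[1, j] + h[1, i] * h[2, j],
                h[2, i] * h[2, j],
            ]
        )

    rows = []
    for h in hs:
        rows.append(v(h, 0, 1))
        rows.append(v(h, 0, 0) - v(h, 1, 1))
    a = np.array(rows)
    _, s, vt = np.linalg.svd(a)
    b = vt[-1]
    if b[0] < 0:
        b = -b
    b11, b22, b13, b23, b33 = b
    if b11 <= 0 or b22 <= 0:
        raise CalibrationDegenerateError("degenerate view set (conic constraints unsolvable)")
    cx = -b13 / b11
    cy = -b23 / b22
    lam = b33 - (b13**2 / b11 + b23**2 / b22)
    if lam <= 0:
        raise CalibrationDegenerateError("degenerate view set (negative conic scale)")
    fx = np.sqrt(lam / b11)
    fy = np.sqrt(lam / b22)
    return float((fx + fy) / 2), float(cx), float(cy)


def _extrinsics_from_homography(h: np.ndarray, f: float, cx: float, cy: float):
    k_inv = np.array([[1 / f, 0, -cx / f], [0, 1 / f, -cy / f], [0, 0, 1.0]])
    a = k_inv @ h
    lam = 1.0 / np.linalg.norm(a[:, 0])
    r1 = lam * a[:, 0]
    r2 = lam * a[:, 1]
    t = lam * a[:, 2]
    if t[2] < 0:  # board must be in front of the camera
        r1, r2, t = -r1, -r2, -t
    r3 = np.cross(r1, r2)
    u, _, vt = np.linalg.svd(np.column_stack([r1, r2, r3]))
    r = u @ vt
    if np.linalg.det(r) < 0:
        r = u @ np.diag([1, 1, -1]) @ vt
    return r, t


def _project_with(f, cx, cy, dist, pts_cam) -> np.ndarray:
    xy = pts_cam[:, :2] / pts_cam[:, 2:3]
    xy = _distort_normalized(np.asarray(dist, dtype=float), xy)
    return xy * f + np.array([cx, cy])


def _mean_rotation(rotations: list[np.ndarray]) -> np.ndarray:
    quats = np.array([Rotation.from_matrix(r).as_quat() for r in rotations])
    quats[quats @ quats[0] < 0] *= -1
    mean = quats.mean(axis=0)
    return Rotation.from_quat(mean / np.linalg.norm(mean)).as_matrix()


def estimate_stereo_calibration(
    observations,
    board: CheckerboardSpec,
    image_size_left: tuple[int, int] | None = None,
    image_size_right: tuple[int, int] | None = None,
) -> CalibrationResult:
    """Fit a full stereo rig to checkerboard corner observations.

    ``observations`` is a sequence of per-view ``(left_corners,
    right_corners)`` pixel arrays, each of shape (N, 2) with N the board's
    inner-corner count, in the board's canonical corner order (objects
    from :func:`stereonav.synthetic.make_checkerboard_views` work
    directly).  At least three views with full corner sets are required.
    """
    if hasattr(observations, "views"):
        if image_size_left is None:
            image_size_left = observations.image_size_left
            image_size_right = observations.image_size_right
        observations = observations.views
    views = [(np.asarray(l, dtype=float), np.asarray(r, dtype=float)) for l, r in observations]
    n_views = len(views)
    if n_views < 3:
        raise CalibrationDegenerateError(f"need >= 3 checkerboard views, got {n_views}")
    n_corners = board.corner_count
    for li, ri in views:
        if li.shape != (n_corners, 2) or ri.shape != (n_corners, 2):
            raise CalibrationDegenerateError("every view needs the full corner set in both cameras")
    obj = board.object_points()
    obj_xy = obj[:, :2]

    hs_l = [_homography_dlt(obj_xy, li) for li, _ in views]
    hs_r = [_homography_dlt(obj_xy, ri) for _, ri in views]
    f_l, cx_l, cy_l = _intrinsics_from_homographies(hs_l, image_size_left)
    f_r, cx_r, cy_r = _intrinsics_from_homographies(hs_r, image_size_right)

    poses_l = [_extrinsics_from_homography(h, f_l, cx_l, cy_l) for h in hs_l]
    poses_r = [_extrinsics_from_homography(h, f_r, cx_r, cy_r) for h in hs_r]

    # relative pose: x_r = R_rel (x_l - t_rel), averaged over views
    r_rels, t_rels = [], []
    for (rl, tl), (rr, tr) in zip(poses_l, poses_r):
        r_rel = rr @ rl.T
        c_r_world = -rr.T @ tr
        t_rels.append(rl @ c_r_world + tl)
        r_rels.append(r_rel)
    r_rel0 = _mean_rotation(r_rels)
    t_rel0 = np.mean(t_rels, axis=0)

    # ---- joint refinement ----------------------------------------------
    def pack():
        p = [f_l, cx_l, cy_l, *np.zeros(5), f_r, cx_r, cy_r, *np.zeros(5)]
        p += list(Rotation.from_matrix(r_rel0).as_rotvec()) + list(t_rel0)
        for rl, tl in poses_l:
            p += list(Rotation.from_matrix(rl).as_rotvec()) + list(tl)
        return np.array(p, dtype=float)

    def unpack(p):
        intr_l = (p[0], p[1], p[2], p[3:8])
        intr_r = (p[8], p[9], p[10], p[11:16])
        r_rel = Rotation.from_rotvec(p[16:19]).as_matrix()
        t_rel = p[19:22]
        poses = []
        for i in range(n_views):
            s = 22 + 6 * i
            poses.append((Rotation.from_rotvec(p[s : s + 3]).as_matrix(), p[s + 3 : s + 6]))
        return intr_l, intr_r, r_rel, t_rel, poses

    def residuals(p):
        intr_l, intr_r, r_rel, t_rel, poses = unpack(p)
        res = []
        for (li, ri), (rl, tl) in zip(views, poses):
            pts_l = obj @ rl.T + tl
            pts_r = (pts_l - t_rel) @ r_rel.T
            res.append((_project_with(*intr_l, pts_l) - li).ravel())
            res.append((_project_with(*intr_r, pts_r) - ri).ravel())
        return np.concatenate(res)

    sol = least_squares(residuals, pack(), method="trf", x_scale="jac", max_nfev=400)
    intr_l, intr_r, r_rel, t_rel, poses = unpack(sol.x)

    # per-view reprojection errors of the final fit
    errs = []
    for (li, ri), (rl, tl) in zip(views, poses):
        pts_l = obj @ rl.T + tl
        pts_r = (pts_l - t_rel) @ r_rel.T
        e_l = mean_reprojection_error(li, _project_with(*intr_l, pts_l))
        e_r = mean_reprojection_error(ri, _project_with(*intr_r, pts_r))
        errs.append((e_l + e_r) / 2)
    errs = np.asarray(errs)

    if image_size_left is None:
        all_l = np.concatenate([li for li, _ in views])
        image_size_left = (int(np.ceil(all_l[:, 0].max())) + 1, int(np.ceil(all_l[:, 1].max())) + 1)
    if image_size_right is None:
        all_r = np.concatenate([ri for _, ri in views])
        image_size_right = (int(np.ceil(all_r[:, 0].max())) + 1, int(np.ceil(all_r[:, 1].max())) + 1)

    left = CameraIntrinsics(intr_l[0], (intr_l[1], intr_l[2]), image_size_left, intr_l[3])
    right = CameraIntrinsics(intr_r[0], (intr_r[1], intr_r[2]), image_size_right, intr_r[3])
    baseline = float(np.linalg.norm(t_rel))
    tx = -baseline if t_rel[0] >= 0 else baseline
    rig = StereoRig(
        left=left,
        right=right,
        rotation=r_rel,
        translation=np.asarray(t_rel, dtype=float),
        rectified_focal=(left.focal_length_px + right.focal_length_px) / 2,
        rectified_left_principal=left.principal_point_px,
        rectified_right_principal_x=right.principal_point_px[0],
        baseline_tx_mm=tx,
    )
    return CalibrationResult(
        rig=rig,
        mean_reprojection_error_px=float(errs.mean()),
        per_view_errors_px=errs,
        board_poses=[(Rotation.from_matrix(r).as_rotvec(), t) for r, t in poses],
    )
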