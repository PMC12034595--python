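"""Synthetic study scenes with exact ground truth.

Every input the reconstruction/registration pipeline consumes can be
generated here with known truth: calibrated rigs matching the printed
endoscope matrices, checkerboard corner observations for calibration,
branching tubular "arterial" meshes with named bifurcation landmarks,
stereo renders with per-pixel true disparity/depth and an occlusion mask,
instrument-like occluders that cut gaps into the reconstructed cloud, and
a known rigid displacement standing in for the preoperative-to-
intraoperative pose change.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from .camera import CheckerboardSpec, StereoRig, project_point
from .errors import StereoNavError
from .overlay import SurfaceMesh
from .preprocess import StereoFrame
from .register import LandmarkSet, RigidTransform, apply_transform
from .render import rasterize_triangles, value_noise3
from .stereo import DisparityMap
from .cloud import cloud_from_disparity, pick_landmark_3d

__all__ = [
    "make_rig",
    "CheckerboardObservations",
    "make_checkerboard_views",
    "make_vessel_tree",
    "render_synthetic_stereo",
    "SyntheticScene",
    "make_scene",
    "perturb_scene",
    "measurement_campaign",
]

# Rig presets reproducing the printed endoscope reprojection matrices.
# Baselines are recovered from the (4,3) = -1/T_x entries.
RIG_PRESETS = {
    "vats": dict(focal_px=1432.8, principal=(988.53, 546.98), size=(1920, 1080), baseline_mm=1 / 0.16406),
    "rats": dict(focal_px=1013.3, principal=(672.0, 523.24), size=(1264, 1010), baseline_mm=1 / 0.25266),
    # desk-scale rig used by the synthetic end-to-end studies: roughly the
    # RATS geometry at half resolution, so renders + matching stay in the
    # seconds range while depth resolution at a 90 mm working distance is
    # ~2 mm per pixel of disparity
    "desk": dict(focal_px=840.0, principal=(320.0, 256.0), size=(640, 512), baseline_mm=5.0),
}

# study conditions for generated scenes: a segmental-artery-scale binary
# tree (7 bifurcations) whose branching planes twist between nodes
DEFAULT_TREE_PARAMS = dict(
    depth=3,
    segment_length_mm=14.0,
    length_decay=0.72,
    root_radius_mm=2.2,
    radius_decay=0.8,
    jitter_deg=10.0,
)


def make_rig(
    preset: str = "desk",
    *,
    focal_px: float | None = None,
    principal: tuple[float, float] | None = None,
    image_size: tuple[int, int] | None = None,
    baseline_mm: float | None = None,
) -> StereoRig:
    """Build an ideal (already rectified) stereo rig from a preset.

    Presets: ``vats`` and ``rats`` reproduce the printed endoscope
    intrinsics; ``desk`` is the small synthetic-study rig; ``custom``
    requires all keyword parameters.
    """
    if preset == "custom":
        if None in (focal_px, principal, image_size, baseline_mm):
            raise ValueError("custom preset requires focal_px, principal, image_size, baseline_mm")
        params = dict(focal_px=focal_px, principal=principal, size=image_size, baseline_mm=baseline_mm)
    else:
        try:
            params = dict(RIG_PRESETS[preset])
        except KeyError:
            raise ValueError(f"unknown rig preset {preset!r}") from None
        for key, val in (
            ("focal_px", focal_px),
            ("principal", principal),
            ("size", image_size),
            ("baseline_mm", baseline_mm),
        ):
            if val is not None:
                params[key] = val
    return StereoRig.parallel(
        params["focal_px"], params["principal"], params["size"], params["baseline_mm"]
    )


# --------------------------------------------------------------------------
# checkerboard calibration targets
# --------------------------------------------------------------------------


@dataclass
class CheckerboardObservations:
    """Per-view corner pixel sets for both cameras (+ exact ground truth)."""

    views: list
    exact_views: list
    poses: list  # (R, t) of the board in the left-camera frame
    board: CheckerboardSpec
    image_size_left: tuple[int, int]
    image_size_right: tuple[int, int]
    corner_noise_px: float
    seed: int

    def __len__(self) -> int:
        return len(self.views)


def make_checkerboard_views(
    rig: StereoRig,
    board: CheckerboardSpec,
    n_poses: int,
    seed: int = 0,
    corner_noise_px: float = 0.0,
    *,
    max_retries: int = 200,
) -> CheckerboardObservations:
    """Project the checkerboard from deterministic random poses.

    Each pose keeps the full corner grid inside both camera frusta (with a
    small margin); corner observations are the exact projections plus
    i.i.d. Gaussian noise of the stated sigma.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    rng = np.random.default_rng(seed)
    obj = board.object_points()
    extent = max(
        (board.inner_corner_grid[0] + 1) * board.square_size_mm,
        (board.inner_corner_grid[1] + 1) * board.square_size_mm,
    )
    w_l, h_l = rig.left.image_size
    w_r, h_r = rig.right.image_size
    margin = 8.0

    views, exact_views, poses = [], [], []
    for _ in range(n_poses):
        for attempt in range(max_retries):
            frac = rng.uniform(0.35, 0.6)
            z0 = rig.left.focal_length_px * extent / (frac * min(w_l, h_l))
            tilt_axis = np.append(_unit2(rng), 0.0)
            tilt = Rotation.from_rotvec(tilt_axis * np.deg2rad(rng.uniform(8, 35)))
            inplane = Rotation.from_rotvec([0, 0, rng.uniform(0, 2 * np.pi)])
            r = (tilt * inplane).as_matrix()
            t = np.array(
                [
                    rng.uniform(-0.08, 0.08) * z0 + rig.translation[0] / 2,
                    rng.uniform(-0.08, 0.08) * z0,
                    z0 * rng.uniform(0.95, 1.15),
                ]
            )
            pts_l = obj @ r.T + t
            pts_r = (pts_l - rig.translation) @ rig.rotation.T
            if np.any(pts_l[:, 2] <= 1.0) or np.any(pts_r[:, 2] <= 1.0):
                continue
            px_l = project_point(rig.left, pts_l)
            px_r = project_point(rig.right, pts_r)
            ok_l = np.all((px_l > margin) & (px_l < np.array([w_l, h_l]) - margin))
            ok_r = np.all((px_r > margin) & (px_r < np.array([w_r, h_r]) - margin))
            if ok_l and ok_r:
                break
        else:
            raise StereoNavError("could not sample a board pose inside both frusta")
        noise_l = rng.normal(0, corner_noise_px, px_l.shape) if corner_noise_px > 0 else 0.0
        noise_r = rng.normal(0, corner_noise_px, px_r.shape) if corner_noise_px > 0 else 0.0
        views.append((px_l + noise_l, px_r + noise_r))
        exact_views.append((px_l, px_r))
        poses.append((r, t))
    return CheckerboardObservations(
        views, exact_views, poses, board, (w_l, h_l), (w_r, h_r), corner_noise_px, seed
    )


def _unit2(rng) -> np.ndarray:
    phi = rng.uniform(0, 2 * np.pi)
    return np.array([np.cos(phi), np.sin(phi)])


# --------------------------------------------------------------------------
# vessel trees
# --------------------------------------------------------------------------


def make_vessel_tree(
    seed: int = 0,
    *,
    depth: int = 2,
    root_radius_mm: float = 2.2,
    radius_decay: float = 0.78,
    segment_length_mm: float = 20.0,
    length_decay: float = 0.8,
    branch_angle_deg: float = 35.0,
    jitter_deg: float = 8.0,
    sections: int = 14,
) -> tuple[SurfaceMesh, LandmarkSet]:
    """Branching tubular artery stand-in with bifurcation landmarks.

    A binary tree of ``depth`` bifurcation levels grown from a single
    trunk: depth 0 is one cylinder with no landmarks, depth 2 has three
    bifurcations.  One named landmark sits at each internal branch node
    (on the centerline).  The mesh grows roughly along +x, branching in
    the local x-y plane with 3D jitter, and is expressed in its own local
    frame (pose it with a rigid transform).
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if root_radius_mm <= 0 or segment_length_mm <= 0:
        raise ValueError("radii and segment lengths must be positive")
    rng = np.random.default_rng(seed)
    segments: list[tuple[np.ndarray, np.ndarray, float]] = []
    bifurcations: list[np.ndarray] = []
    bif_radii: list[float] = []

    def grow(start: np.ndarray, direction: np.ndarray, length: float, radius: float, level: int):
        end = start + direction * length
        segments.append((start, end, radius))
        if level >= depth:
            return
        bifurcations.append(end)
        bif_radii.append(radius)
        # branching plane: a fixed-per-node normal jittered in azimuth
        perp = np.cross(direction, [0.0, 1.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(direction, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        # branching planes twist from node to node like real arterial trees,
        # giving the landmark set genuine 3D extent
        perp = Rotation.from_rotvec(direction * np.deg2rad(rng.uniform(-55, 55))).apply(perp)
        for sign in (1.0, -1.0):
            ang = np.deg2rad(branch_angle_deg + rng.uniform(-jitter_deg, jitter_deg))
            child_dir = Rotation.from_rotvec(perp * sign * ang).apply(direction)
            child_dir /= np.linalg.norm(child_dir)
            grow(end, child_dir, length * length_decay, radius * radius_decay, level + 1)

    grow(np.zeros(3), np.array([1.0, 0.0, 0.0]), segment_length_mm, root_radius_mm, 0)

    parts = []
    for s, e, r in segments:
        parts.append(trimesh.creation.cylinder(radius=r, segment=[s, e], sections=sections))
    for b, r in zip(bifurcations, bif_radii):
        sphere = trimesh.creation.icosphere(subdivisions=1, radius=r)
        sphere.apply_translation(b)
        parts.append(sphere)
    tm = trimesh.util.concatenate(parts)
    mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), label="artery")
    names = [f"bif-{i + 1}" for i in range(len(bifurcations))]
    landmarks = LandmarkSet(
        np.asarray(bifurcations).reshape(-1, 3), names, frame="preop"
    ) if bifurcations else LandmarkSet(np.zeros((0, 3)), [], frame="preop")
    return mesh, landmarks


# --------------------------------------------------------------------------
# stereo rendering with ground truth
# --------------------------------------------------------------------------


def _merge_meshes(meshes: Sequence[SurfaceMesh]):
    verts, faces, colors = [], [], []
    offset = 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + offset)
        colors.append(np.tile(np.array(m.color, dtype=float), (len(m.faces), 1)))
        offset += len(m.vertices)
    return np.concatenate(verts), np.concatenate(faces), np.concatenate(colors)


def _shade(raster, verts, faces, face_colors, seed, texture_scale_mm):
    """Stereo-consistent shading: Lambertian (fixed light) x 3D value noise."""
    h, w = raster.depth.shape
    img = np.full((h, w, 3), 25.0)
    mask = raster.mask
    if not mask.any():
        return img.astype(np.uint8)
    fi = raster.face_index[mask]
    tri = verts[faces[fi]]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    n /= np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-12)
    view = raster.points[mask]
    flip = np.sum(n * view, axis=1) > 0  # orient normals toward the camera
    n[flip] *= -1
    light = np.array([-0.25, 0.35, -0.9])
    light /= np.linalg.norm(light)
    diffuse = np.clip(-(n @ light), 0, 1)
    shade = 0.45 + 0.55 * diffuse
    tex = 0.55 + 0.45 * (2 * value_noise3(view, texture_scale_mm, seed, octaves=4) - 1)
    img[mask] = face_colors[fi] * (shade * tex)[:, None]
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def render_synthetic_stereo(
    meshes: Sequence[SurfaceMesh],
    rig: StereoRig,
    *,
    seed: int = 0,
    texture_scale_mm: float = 2.0,
) -> tuple[StereoFrame, DisparityMap, np.ndarray, np.ndarray]:
    """Render camera-frame geometry into both rectified cameras.

    Returns ``(frame, true_disparity, true_depth, occlusion_mask)``.  The
    true disparity at every covered left pixel is ``f |T_x| / Z + (c_x1 -
    c_x2)``; the occlusion mask marks left pixels whose scene point is not
    visible from the right camera (out of view or occluded by nearer
    geometry) — exactly the pixels where matching must fail.

    Requires an ideal parallel rig (rendering happens directly in the
    rectified frames); surface texture is a pure function of the 3D point,
    so the two views are photometrically consistent.
    """
    if not np.allclose(rig.rotation, np.eye(3), atol=1e-9):
        raise ValueError("render_synthetic_stereo requires a parallel (rectified) rig")
    if not any(len(m.faces) for m in meshes):
        raise ValueError("empty scene geometry")
    verts, faces, face_colors = _merge_meshes(meshes)
    w, h = rig.left.image_size
    f = rig.rectified_focal
    cx1, cy = rig.rectified_left_principal
    cx2 = rig.rectified_right_principal_x
    b = rig.baseline_mm

    res_l = rasterize_triangles(verts, faces, f, (cx1, cy), (w, h))
    verts_r = verts - rig.translation
    res_r = rasterize_triangles(verts_r, faces, f, (cx2, cy), (w, h))

    left = _shade(res_l, verts, faces, face_colors, seed, texture_scale_mm)
    # evaluate the right view's texture at left-frame coordinates so the
    # same surface point renders identically in both eyes
    res_r_leftframe = replace(res_r, points=res_r.points + rig.translation)
    right = _shade(res_r_leftframe, verts_r, faces, face_colors, seed, texture_scale_mm)

    depth = np.where(res_l.mask, res_l.depth, np.nan)
    disp = f * b / depth + (cx1 - cx2)
    true_disparity = DisparityMap(
        np.where(res_l.mask, disp, np.nan).astype(np.float32), res_l.mask
    )

    yy, xx = np.mgrid[0:h, 0:w]
    xr = xx - np.where(res_l.mask, disp, 0.0)
    in_right = (xr >= 0) & (xr <= w - 1)
    xr_idx = np.clip(np.round(xr).astype(int), 0, w - 1)
    tol = np.maximum(0.5, 0.01 * np.where(res_l.mask, depth, 1.0))
    right_depth = np.where(res_r.mask, res_r.depth, np.inf)
    occluded_in_right = right_depth[yy, xr_idx] < (np.where(res_l.mask, depth, 0.0) - tol)
    occlusion_mask = res_l.mask & (~in_right | occluded_in_right)

    frame = StereoFrame(left, right, rectified=True, rig=rig)
    return frame, true_disparity, depth, occlusion_mask


# --------------------------------------------------------------------------
# full scenes
# --------------------------------------------------------------------------


@dataclass
class SyntheticScene:
    """A complete ground-truth stereo scene.

    ``displacement`` maps the preoperative frame into the camera frame;
    before noise the landmark pairs satisfy ``k_intraop = R k_preop + t``
    exactly.  ``landmark_pixels`` are the left-image projections of the
    true intraoperative landmarks (the pixels a user would click).
    """

    rig: StereoRig
    meshes_preop: list
    occluders: list
    background: Optional[SurfaceMesh]
    displacement: RigidTransform
    landmarks_preop: LandmarkSet
    landmarks_intraop_true: LandmarkSet
    landmarks_intraop: LandmarkSet
    landmark_pixels: np.ndarray
    frame: StereoFrame
    true_disparity: DisparityMap
    true_depth: np.ndarray
    occlusion_mask: np.ndarray
    seed: int
    landmark_noise_sigma_mm: float = 0.0

    @property
    def meshes_camera(self) -> list:
        return [apply_transform(m, self.displacement) for m in self.meshes_preop]


def make_scene(
    seed: int = 0,
    *,
    rig: StereoRig | None = None,
    tree_params: dict | None = None,
    n_occluders: int = 0,
    background: bool = True,
    texture_scale_mm: float = 2.0,
) -> SyntheticScene:
    """Generate a posed, rendered vessel-tree scene with exact truth.

    The returned scene has identity displacement and noise-free landmark
    pairs (the "preoperative" frame coincides with the camera frame); feed
    it to :func:`perturb_scene` to create a registration problem.

    Landmarks are the visible tube-surface points at each bifurcation
    (depth-map lookup at the projected centerline pixel, tree geometry
    only), mirroring how bifurcation key points are clicked on images;
    each lies within one tube radius of the centerline node.  Bifurcations
    that project outside the image are dropped.
    """
    rig = rig or make_rig("desk")
    rng = np.random.default_rng(seed)
    tree_local, lm_local = make_vessel_tree(seed, **(tree_params or DEFAULT_TREE_PARAMS))

    w, h = rig.left.image_size
    f = rig.rectified_focal
    extent = float(np.ptp(tree_local.vertices, axis=0).max())
    z0 = 1.45 * f * extent / min(w, h)

    # pose: face the branching plane (local x-y) toward the camera with a
    # small random wobble, center the tree on the optical axis
    wobble = Rotation.from_rotvec(rng.normal(0, np.deg2rad(6), 3)).as_matrix()
    center_local = tree_local.vertices.mean(axis=0)
    t_pose = np.array([0.0, 0.0, z0]) - wobble @ center_local
    pose = RigidTransform(wobble, t_pose)

    tree_cam = apply_transform(tree_local, pose)
    lm_cam_pts = pose.apply(lm_local.points)

    occluders = []
    for i in range(n_occluders):
        # a thin instrument-like bar halfway to the i-th bifurcation,
        # oriented across it so it shadows that landmark in both eyes
        target = lm_cam_pts[i % max(len(lm_cam_pts), 1)] if len(lm_cam_pts) else np.array([0, 0, z0])
        box = trimesh.creation.box(extents=(4.0, extent * 0.8, 2.5))
        ang = rng.uniform(-0.4, 0.4)
        rot = Rotation.from_rotvec([0, 0, ang]).as_matrix()
        box.apply_transform(np.vstack([np.column_stack([rot, target * 0.55]), [0, 0, 0, 1]]))
        occluders.append(SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces), label="instrument"))

    bg = None
    scene_meshes = [tree_cam] + occluders
    if background:
        z_bg = z0 + extent * 0.7
        half_w = (w / f) * z_bg * 0.75
        half_h = (h / f) * z_bg * 0.75
        bg_verts = np.array(
            [[-half_w, -half_h, z_bg], [half_w, -half_h, z_bg], [half_w, half_h, z_bg], [-half_w, half_h, z_bg]]
        )
        bg = SurfaceMesh(bg_verts, np.array([[0, 1, 2], [0, 2, 3]]), label="surface")
        scene_meshes.append(bg)

    frame, true_disparity, true_depth, occlusion_mask = render_synthetic_stereo(
        scene_meshes, rig, seed=seed, texture_scale_mm=texture_scale_mm
    )

    # landmark snapping on the tree geometry alone (occluders must not
    # displace the true landmark, they only hide it from the matcher)
    cx1, cy = rig.rectified_left_principal
    res_tree = rasterize_triangles(tree_cam.vertices, tree_cam.faces, f, (cx1, cy), (w, h))
    snapped, pixels, names = [], [], []
    for name, p in zip(lm_local.names, lm_cam_pts):
        if p[2] <= 0:
            continue
        x = int(round(f * p[0] / p[2] + cx1))
        y = int(round(f * p[1] / p[2] + cy))
        if not (0 <= x < w and 0 <= y < h) or not np.isfinite(res_tree.depth[y, x]):
            continue
        snapped.append(res_tree.points[y, x])
        pixels.append((x, y))
        names.append(name)
    lm_true = LandmarkSet(np.asarray(snapped).reshape(-1, 3), names, frame="intraop")

    return SyntheticScene(
        rig=rig,
        meshes_preop=[tree_cam],
        occluders=occluders,
        background=bg,
        displacement=RigidTransform.identity(),
        landmarks_preop=LandmarkSet(lm_true.points.copy(), list(names), frame="preop"),
        landmarks_intraop_true=lm_true,
        landmarks_intraop=LandmarkSet(lm_true.points.copy(), list(names), frame="intraop"),
        landmark_pixels=np.asarray(pixels, dtype=int).reshape(-1, 2),
        frame=frame,
        true_disparity=true_disparity,
        true_depth=true_depth,
        occlusion_mask=occlusion_mask,
        seed=seed,
    )


def random_rigid(
    rng,
    *,
    max_angle_deg: float = 25.0,
    max_offset_mm: float = 20.0,
    anatomy_center: np.ndarray | None = None,
) -> RigidTransform:
    """Seeded random rigid displacement (uniform axis, bounded angle).

    When ``anatomy_center`` (camera-frame mm) is given, the translation is
    chosen so that the displaced ("preoperative") copy of the anatomy lands
    within ``max_offset_mm`` of its own frame's origin — the way a CT
    segmentation's coordinates sit near the scan isocenter rather than tens
    of centimeters away.
    """
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.uniform(0.3 * max_angle_deg, max_angle_deg))
    r = Rotation.from_rotvec(axis * ang).as_matrix()
    delta = rng.uniform(-max_offset_mm, max_offset_mm, 3)
    if anatomy_center is None:
        return RigidTransform(r, delta)
    return RigidTransform(r, np.asarray(anatomy_center, dtype=float) - r @ delta)


def perturb_scene(
    scene: SyntheticScene,
    displacement: RigidTransform | None = None,
    landmark_noise_sigma_mm: float = 0.0,
    seed: int = 0,
) -> SyntheticScene:
    """Create the registration problem: displaced preop copies + noisy picks.

    The preoperative meshes and landmarks are pulled back by the inverse
    displacement (so the stored displacement maps preop -> camera), and
    the intraoperative landmark picks get i.i.d. isotropic Gaussian noise
    of the given sigma.  The ground-truth displacement is retained for
    scoring.
    """
    if landmark_noise_sigma_mm < 0:
        raise ValueError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed)
    if displacement is not None:
        disp = displacement
    else:
        if len(scene.landmarks_intraop_true):
            center = scene.landmarks_intraop_true.points.mean(axis=0)
        else:
            center = np.concatenate([m.vertices for m in scene.meshes_camera]).mean(axis=0)
        disp = random_rigid(rng, anatomy_center=center)
    inv = disp.inverse()
    total = disp.compose(scene.displacement)
    meshes_preop = [apply_transform(m, inv) for m in scene.meshes_preop]
    lm_preop = replace(
        scene.landmarks_preop, points=inv.apply(scene.landmarks_preop.points), frame="preop"
    )
    noisy = scene.landmarks_intraop_true.points + (
        rng.normal(0, landmark_noise_sigma_mm, scene.landmarks_intraop_true.points.shape)
        if landmark_noise_sigma_mm > 0
        else 0.0
    )
    return replace(
        scene,
        meshes_preop=meshes_preop,
        displacement=total,
        landmarks_preop=lm_preop,
        landmarks_intraop=replace(scene.landmarks_intraop_true, points=noisy),
        landmark_noise_sigma_mm=landmark_noise_sigma_mm,
    )


# --------------------------------------------------------------------------
# measurement validation campaign
# --------------------------------------------------------------------------


def measurement_campaign(
    seed: int = 0,
    n_objects: int = 20,
    disparity_noise_px: float = 0.25,
    rig: StereoRig | None = None,
    pick_window: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Measure known-diameter cylinders and instrument bars on the cloud.

    Emulates the clinical validation: for each synthetic vessel cylinder
    or instrument bar of known width, the ground-truth disparity map is
    perturbed with Gaussian disparity noise, reprojected to a cloud, and
    the diameter measured between the two silhouette-edge picks on the row
    through the object center.  Returns ``(measured, reference)`` in mm.
    """
    rig = rig or make_rig("rats")
    rng = np.random.default_rng(seed)
    w, h = rig.left.image_size
    f = rig.rectified_focal
    cx1, cy = rig.rectified_left_principal
    q = rig.q_matrix
    measured, reference = [], []
    for i in range(n_objects):
        diameter = rng.uniform(3.0, 10.0)
        z0 = rng.uniform(60.0, 120.0)
        length = rng.uniform(30.0, 50.0)
        if i % 2 == 0:  # vessel stand-in: vertical cylinder
            tm = trimesh.creation.cylinder(radius=diameter / 2, height=length, sections=48)
            rot = Rotation.from_rotvec([np.pi / 2 + rng.normal(0, 0.05), 0, 0]).as_matrix()
        else:  # instrument stand-in: flat bar, front face toward camera
            tm = trimesh.creation.box(extents=(diameter, length, 4.0))
            rot = Rotation.from_rotvec([0, 0, rng.normal(0, 0.05)]).as_matrix()
        verts = np.asarray(tm.vertices) @ rot.T + np.array(
            [rng.uniform(-3, 3), rng.uniform(-3, 3), z0]
        )
        res = rasterize_triangles(verts, np.asarray(tm.faces), f, (cx1, cy), (w, h))
        depth = np.where(res.mask, res.depth, np.nan)
        disp = f * rig.baseline_mm / depth
        disp += rng.normal(0, disparity_noise_px, disp.shape)
        dmap = DisparityMap(disp.astype(np.float32), res.mask)
        cloud = cloud_from_disparity(dmap, q, np.zeros((h, w), dtype=np.uint8))
        # row through the object center
        y0 = int(round(f * (verts.mean(axis=0)[1]) / z0 + cy))
        y0 = int(np.clip(y0, 0, h - 1))
        row_valid = np.nonzero(res.mask[y0])[0]
        if row_valid.size < 2:
            continue
        xa, xb = int(row_valid[0]), int(row_valid[-1])
        pa = pick_landmark_3d(cloud, (xa, y0), pick_window)
        pb = pick_landmark_3d(cloud, (xb, y0), pick_window)
        measured.append(float(np.linalg.norm(pa - pb)))
        reference.append(diameter)
    return np.asarray(measured), np.asarray(reference)
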