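"""Depth-aware augmented-reality overlay rendering.

The registered preoperative meshes (arteries, veins, bronchi, tumor) are
rasterized onto the intraoperative left image with a z-buffer.  Fragments
nearer than the reconstructed surface composite at the structure's
opacity; fragments *behind* the visible surface stay visible but
attenuated (opacity times a behind-surface multiplier), which is how
hidden anatomy — a bronchus behind an artery, a tumor inside parenchyma —
is shown through the tissue.  Branch labels are drawn at projected
landmark anchors; a spherical crop and per-structure visibility toggles
cut the scene down to the surgical region of interest, and a zoom factor
scales the focal length for a zoomed-out context view.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .camera import CameraIntrinsics
from .cloud import PointCloud
from .errors import MeshError
from .register import LandmarkSet, RigidTransform
from .render import rasterize_triangles

__all__ = [
    "SurfaceMesh",
    "OverlayStyle",
    "STRUCTURE_COLORS",
    "depth_buffer_from_cloud",
    "render_overlay",
    "crop_to_region",
]

STRUCTURE_LABELS = ("artery", "vein", "bronchus", "tumor", "instrument", "surface")

# fixed default color scheme: artery red, vein blue, bronchus green, tumor yellow
STRUCTURE_COLORS = {
    "artery": (220, 40, 40),
    "vein": (50, 70, 220),
    "bronchus": (50, 190, 70),
    "tumor": (235, 220, 50),
    "instrument": (120, 120, 130),
    "surface": (185, 140, 120),
}


@dataclass
class SurfaceMesh:
    """Triangle mesh P(F, V) of one anatomical structure, units mm."""

    vertices: np.ndarray
    faces: np.ndarray
    label: str = "artery"
    color: Optional[tuple[int, int, int]] = None
    opacity: float = 1.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.label not in STRUCTURE_LABELS:
            raise MeshError(f"unknown structure label {self.label!r}; expected one of {STRUCTURE_LABELS}")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshError("face indices out of range")
        if not 0.0 <= self.opacity <= 1.0:
            raise ValueError("opacity must lie in [0, 1]")
        if self.color is None:
            self.color = STRUCTURE_COLORS[self.label]

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0


@dataclass
class OverlayStyle:
    """Rendering style: toggles, opacities, labels, crop, zoom."""

    visible: dict = field(default_factory=dict)
    opacity: dict = field(default_factory=dict)
    behind_surface_multiplier: float = 0.4
    show_labels: bool = True
    label_anchors: Optional[LandmarkSet] = None
    crop_center: Optional[np.ndarray] = None
    crop_radius_mm: Optional[float] = None
    zoom: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.behind_surface_multiplier <= 1.0:
            raise ValueError("behind-surface multiplier must lie in [0, 1]")
        for v in self.opacity.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("opacities must lie in [0, 1]")
        if self.crop_radius_mm is not None and self.crop_radius_mm <= 0:
            raise ValueError("crop radius must be positive when set")
        if self.crop_center is not None:
            self.crop_center = np.asarray(self.crop_center, dtype=float).reshape(3)

    def structure_opacity(self, mesh: SurfaceMesh) -> float:
        return float(self.opacity.get(mesh.label, mesh.opacity))

    def structure_visible(self, mesh: SurfaceMesh) -> bool:
        return bool(self.visible.get(mesh.label, True))


def depth_buffer_from_cloud(cloud: PointCloud) -> np.ndarray:
    """Per-pixel depth (mm) of an organized cloud; NaN where invalid."""
    if not cloud.organized:
        raise ValueError("depth_buffer_from_cloud requires an organized cloud")
    h, w = cloud.index_map.shape
    buf = np.full((h, w), np.nan)
    xs, ys = cloud.pixel_provenance[:, 0], cloud.pixel_provenance[:, 1]
    buf[ys, xs] = cloud.points[:, 2]
    return buf


def crop_to_region(meshes, center, radius_mm: float):
    """Keep only faces whose vertices all lie inside the given sphere.

    Accepts one mesh or a sequence; an empty result is allowed (the crop
    is a viewing aid, not a validity constraint).
    """
    if radius_mm <= 0:
        raise ValueError("crop radius must be positive")
    center = np.asarray(center, dtype=float).reshape(3)
    single = isinstance(meshes, SurfaceMesh)
    mesh_list = [meshes] if single else list(meshes)
    out = []
    for mesh in mesh_list:
        inside = np.linalg.norm(mesh.vertices - center, axis=1) <= radius_mm
        keep = inside[mesh.faces].all(axis=1) if len(mesh.faces) else np.zeros(0, dtype=bool)
        faces = mesh.faces[keep]
        used = np.unique(faces)
        remap = np.full(len(mesh.vertices), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        out.append(
            replace(mesh, vertices=mesh.vertices[used] if len(used) else np.zeros((0, 3)),
                    faces=remap[faces] if len(faces) else np.zeros((0, 3), dtype=np.int64))
        )
    return out[0] if single else out


def _draw_labels(image: np.ndarray, anchors: LandmarkSet, intr: CameraIntrinsics, focal: float) -> np.ndarray:
    from PIL import Image, ImageDraw

    cx, cy = intr.principal_point_px
    h, w = image.shape[:2]
    pil = Image.fromarray(image)
    draw = ImageDraw.Draw(pil)
    for name, p in zip(anchors.names, anchors.points):
        if p[2] <= 0:
            continue
        x = focal * p[0] / p[2] + cx
        y = focal * p[1] / p[2] + cy
        if not (0 <= x < w and 0 <= y < h):
            continue
        # 1-px black outline, white core; no occlusion test for text
        for dx, dy in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            draw.text((x + 3 + dx, y - 8 + dy), name, fill=(0, 0, 0))
        draw.text((x + 3, y - 8), name, fill=(255, 255, 255))
    return np.asarray(pil)


def render_overlay(
    image: np.ndarray,
    cloud: Optional[PointCloud],
    meshes: Sequence[SurfaceMesh],
    transform: RigidTransform,
    intrinsics: CameraIntrinsics,
    style: Optional[OverlayStyle] = None,
) -> np.ndarray:
    """Composite registered preoperative meshes onto the left image.

    Meshes are given in the preoperative frame; ``transform`` maps them
    into the rectified left-camera frame.  Per-pixel compositing is
    back-to-front by fragment depth against the cloud's depth buffer.
    Returns a new image of the same shape; with nothing to draw the input
    is returned unchanged (byte-identical copy).
    """
    style = style or OverlayStyle()
    image = np.asarray(image)
    h, w = image.shape[:2]
    focal = intrinsics.focal_length_px * style.zoom

    surface_depth = depth_buffer_from_cloud(cloud) if cloud is not None and len(cloud) else None

    layers = []  # (depth H,W, color 3, alpha_eff H,W)
    for mesh in meshes:
        if mesh.is_empty or not style.structure_visible(mesh):
            continue
        alpha = style.structure_opacity(mesh)
        if alpha == 0.0:
            continue
        verts = transform.apply(mesh.vertices)
        faces = mesh.faces
        if style.crop_center is not None and style.crop_radius_mm is not None:
            cropped = crop_to_region(
                replace(mesh, vertices=verts), transform.apply(style.crop_center), style.crop_radius_mm
            )
            verts, faces = cropped.vertices, cropped.faces
            if len(faces) == 0:
                continue
        res = rasterize_triangles(
            verts, faces, focal, intrinsics.principal_point_px, (w, h)
        )
        if not res.mask.any():
            continue
        a = np.where(res.mask, alpha, 0.0)
        if surface_depth is not None and style.behind_surface_multiplier != 1.0:
            behind = res.mask & np.isfinite(surface_depth) & (res.depth > surface_depth)
            a = np.where(behind, a * style.behind_surface_multiplier, a)
        layers.append((res.depth, np.array(mesh.color, dtype=float), a))

    out = image.astype(float).copy()
    if layers:
        depths = np.stack([ly[0] for ly in layers])
        alphas = np.stack([ly[2] for ly in layers])
        colors = np.stack([ly[1] for ly in layers])
        # back-to-front: farther fragments composited first
        order = np.argsort(-np.where(np.isfinite(depths), depths, -np.inf), axis=0, kind="stable")
        for rank in range(len(layers)):
            li = order[rank]  # (H, W) layer index per pixel
            a = np.take_along_axis(alphas, li[None], axis=0)[0]
            col = colors[li]  # (H, W, 3)
            if image.ndim == 3:
                out = out * (1 - a[..., None]) + col * a[..., None]
            else:
                out = out * (1 - a) + col.mean(axis=-1) * a
    result = np.clip(np.round(out), 0, 255).astype(np.uint8)

    if style.show_labels and style.label_anchors is not None and len(style.label_anchors):
        anchors_cam = replace(style.label_anchors, points=transform.apply(style.label_anchors.points))
        result = _draw_labels(result, anchors_cam, intrinsics, focal)
    return result
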