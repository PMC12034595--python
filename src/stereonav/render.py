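"""Deterministic software rasterization (internal).

A plain z-buffered triangle rasterizer over numpy: perspective projection,
screen-space barycentric coverage, perspective-correct depth and 3D-point
interpolation.  Deterministic and dependency-free by design — scene sizes
in this package are desk-scale, so testability wins over GPU speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RasterResult", "rasterize_triangles", "value_noise3"]


@dataclass
class RasterResult:
    """Per-pixel rasterization output.

    ``depth`` is +inf where nothing was drawn, ``face_index`` -1, and
    ``points`` the perspective-correct camera-frame 3D point (mm).
    """

    depth: np.ndarray
    face_index: np.ndarray
    points: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.depth)


def rasterize_triangles(
    vertices: np.ndarray,
    faces: np.ndarray,
    focal_px: float,
    principal_point_px: tuple[float, float],
    image_size: tuple[int, int],
    *,
    znear: float = 1.0,
) -> RasterResult:
    """Rasterize camera-frame triangles into a z-buffer.

    Faces with any vertex closer than ``znear`` (mm) are dropped rather
    than clipped; scenes generated by this package keep geometry well in
    front of the camera.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    w, h = image_size
    cx, cy = principal_point_px
    depth = np.full((h, w), np.inf)
    face_index = np.full((h, w), -1, dtype=np.int64)
    points = np.zeros((h, w, 3))
    if len(faces) == 0:
        return RasterResult(depth, face_index, points)
    if faces.min() < 0 or faces.max() >= len(vertices):
        raise IndexError("face indices out of range")

    z = vertices[:, 2]
    px = focal_px * vertices[:, 0] / z + cx
    py = focal_px * vertices[:, 1] / z + cy
    proj = np.column_stack([px, py])

    tri_z = z[faces]
    front = np.all(tri_z > znear, axis=1)

    for fi in np.nonzero(front)[0]:
        i0, i1, i2 = faces[fi]
        p0, p1, p2 = proj[i0], proj[i1], proj[i2]
        xmin = max(int(np.floor(min(p0[0], p1[0], p2[0]))), 0)
        xmax = min(int(np.ceil(max(p0[0], p1[0], p2[0]))), w - 1)
        ymin = max(int(np.floor(min(p0[1], p1[1], p2[1]))), 0)
        ymax = min(int(np.ceil(max(p0[1], p1[1], p2[1]))), h - 1)
        if xmin > xmax or ymin > ymax:
            continue
        area = (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p1[1] - p0[1]) * (p2[0] - p0[0])
        if abs(area) < 1e-12:
            continue
        xs = np.arange(xmin, xmax + 1, dtype=float)
        ys = np.arange(ymin, ymax + 1, dtype=float)
        gx, gy = np.meshgrid(xs, ys)
        w0 = ((p1[0] - p0[0]) * (gy - p0[1]) - (p1[1] - p0[1]) * (gx - p0[0])) / area
        w1 = ((p2[0] - p1[0]) * (gy - p1[1]) - (p2[1] - p1[1]) * (gx - p1[0])) / area
        w2 = 1.0 - w0 - w1
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        # barycentric weights w.r.t. (p0, p1, p2): lambda0 = w1', etc.
        l0, l1, l2 = w1, w2, w0
        inv_z = l0 / tri_z[fi][0] + l1 / tri_z[fi][1] + l2 / tri_z[fi][2]
        zpix = 1.0 / inv_z
        sub_d = depth[ymin : ymax + 1, xmin : xmax + 1]
        win = inside & (zpix < sub_d)
        if not win.any():
            continue
        pt = (
            l0[..., None] * vertices[i0] / tri_z[fi][0]
            + l1[..., None] * vertices[i1] / tri_z[fi][1]
            + l2[..., None] * vertices[i2] / tri_z[fi][2]
        ) * zpix[..., None]
        sub_d[win] = zpix[win]
        face_index[ymin : ymax + 1, xmin : xmax + 1][win] = fi
        points[ymin : ymax + 1, xmin : xmax + 1][win] = pt[win]
    return RasterResult(depth, face_index, points)


def _hash_lattice(ix: np.ndarray, iy: np.ndarray, iz: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic integer-lattice hash mapped to [0, 1)."""
    h = (
        ix.astype(np.uint64) * np.uint64(73856093)
        ^ iy.astype(np.uint64) * np.uint64(19349663)
        ^ iz.astype(np.uint64) * np.uint64(83492791)
        ^ np.uint64(seed & 0x7FFFFFFF)
    )
    h = (h * np.uint64(2654435761)) & np.uint64(0xFFFFFFFF)
    h ^= h >> np.uint64(16)
    h = (h * np.uint64(2246822519)) & np.uint64(0xFFFFFFFF)
    return (h & np.uint64(0xFFFFFF)).astype(float) / float(0x1000000)


def value_noise3(points: np.ndarray, scale_mm: float, seed: int = 0, octaves: int = 3) -> np.ndarray:
    """Band-limited value noise evaluated at 3D points (mm), in [0, 1].

    A pure function of (point, scale, seed): the same surface point gets
    the same value in every camera, which is what makes the procedurally
    textured renders stereo-consistent and block-matchable.
    """
    points = np.asarray(points, dtype=float)
    out = np.zeros(points.shape[:-1])
    amp_total = 0.0
    for o in range(octaves):
        freq = 2.0**o
        amp = 0.5**o
        p = points * (freq / scale_mm)
        p0 = np.floor(p)
        frac = p - p0
        t = frac * frac * (3 - 2 * frac)  # smoothstep
        ix, iy, iz = (p0[..., i].astype(np.int64) for i in range(3))
        val = np.zeros(points.shape[:-1])
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    corner = _hash_lattice(ix + dx, iy + dy, iz + dz, seed + 101 * o)
                    wx = t[..., 0] if dx else 1 - t[..., 0]
                    wy = t[..., 1] if dy else 1 - t[..., 1]
                    wz = t[..., 2] if dz else 1 - t[..., 2]
                    val += corner * wx * wy * wz
        out += amp * val
        amp_total += amp
    return out / amp_total
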