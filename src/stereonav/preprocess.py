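"""Raw capture handling: VATS de-interlacing, undistortion, rectification.

The VATS capture chain delivers a single frame in which the left and right
eye views are row-interlaced; the RATS chain delivers separate streams.
Both are reduced to the same intermediate: an undistorted, row-aligned
(rectified) stereo pair in which corresponding scene points share an image
row, so that the disparity search becomes one-dimensional.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from .camera import CameraIntrinsics, StereoRig, _denormalize, _distort_normalized
from .errors import DimensionMismatchError, InterlaceParityError

__all__ = ["StereoFrame", "deinterlace_vats", "interlace", "rectify_pair", "rectifying_rotations"]


@dataclass
class StereoFrame:
    """A left/right image pair, optionally rectified."""

    left_image: np.ndarray
    right_image: np.ndarray
    rectified: bool = False
    rig: Optional[StereoRig] = None

    def __post_init__(self) -> None:
        if self.left_image.shape != self.right_image.shape:
            raise DimensionMismatchError(
                f"left/right image shapes differ: {self.left_image.shape} vs {self.right_image.shape}"
            )

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.left_image.shape[:2]


def _upsample_rows(half: np.ndarray, parity_offset: int, full_height: int, method: str) -> np.ndarray:
    """Restore a half-height field to full height.

    The field's rows occupy rows ``parity_offset, parity_offset+2, ...`` of
    the output; the missing rows are filled by linear interpolation between
    neighboring field rows (or row replication for ``method='nearest'``).
    """
    out_rows = np.arange(full_height, dtype=float)
    # position of each output row in field-row units
    src = (out_rows - parity_offset) / 2.0
    src = np.clip(src, 0, half.shape[0] - 1)
    if method == "nearest":
        src = np.round(src)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, half.shape[0] - 1)
    w = (src - lo).astype(half.dtype if np.issubdtype(half.dtype, np.floating) else float)
    shape = (-1,) + (1,) * (half.ndim - 1)
    out = half[lo] * (1 - w.reshape(shape)) + half[hi] * w.reshape(shape)
    if np.issubdtype(half.dtype, np.integer):
        out = np.round(out).astype(half.dtype)
    return out


def deinterlace_vats(
    frame: np.ndarray, *, parity: str = "even-left", method: str = "linear"
) -> tuple[np.ndarray, np.ndarray]:
    """Split a row-interlaced stereo frame into left and right images.

    Rows 0, 2, 4, ... (0-based) form one eye and rows 1, 3, 5, ... the
    other; each half-height field is restored to full height by linear row
    interpolation.  Which parity carries the left eye is hardware-dependent
    and controlled by ``parity`` ('even-left' or 'odd-left').
    """
    frame = np.asarray(frame)
    h = frame.shape[0]
    if h < 2 or h % 2 != 0:
        raise InterlaceParityError(f"interlaced frame height must be even and >= 2, got {h}")
    if parity not in ("even-left", "odd-left"):
        raise ValueError(f"parity must be 'even-left' or 'odd-left', got {parity!r}")
    even = _upsample_rows(frame[0::2], 0, h, method)
    odd = _upsample_rows(frame[1::2], 1, h, method)
    return (even, odd) if parity == "even-left" else (odd, even)


def interlace(left: np.ndarray, right: np.ndarray, *, parity: str = "even-left") -> np.ndarray:
    """Build a row-interlaced frame from a stereo pair (testing aid)."""
    if left.shape != right.shape:
        raise DimensionMismatchError("left/right shapes differ")
    if left.shape[0] % 2 != 0:
        raise InterlaceParityError("height must be even")
    out = np.empty_like(left)
    if parity == "even-left":
        out[0::2], out[1::2] = left[0::2], right[1::2]
    elif parity == "odd-left":
        out[0::2], out[1::2] = right[0::2], left[1::2]
    else:
        raise ValueError(f"unknown parity {parity!r}")
    return out


def _half_rotation(r: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_matrix(r)
    return Rotation.from_rotvec(rot.as_rotvec() / 2).as_matrix()


def rectifying_rotations(rig: StereoRig) -> tuple[np.ndarray, np.ndarray]:
    """Rotations R_l, R_r that bring both cameras into the rectified frame.

    After applying ``x' = R_l x`` (left) and ``x' = R_r x`` (right) the two
    camera frames are parallel and the baseline lies along +x, so epipolar
    lines coincide with image rows.  The relative rotation is split evenly
    between the two cameras (minimal total rotation), then both are turned
    so the new x-axis points along the baseline.
    """
    r_half = _half_rotation(rig.rotation)
    # baseline (right camera center) expressed in the half-rotated left frame
    b = r_half @ rig.translation
    e1 = b / np.linalg.norm(b)
    # choose e2 orthogonal to e1 and to the average optical axis
    z = np.array([0.0, 0.0, 1.0])
    e2 = np.cross(z, e1)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    r_align = np.vstack([e1, e2, e3])
    r_l = r_align @ r_half
    r_r = r_l @ rig.rotation.T
    return r_l, r_r


def _build_remap(
    intr: CameraIntrinsics,
    r_cam: np.ndarray,
    rect_f: float,
    rect_c: tuple[float, float],
    size: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    w, h = size
    u, v = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    dirs = np.stack([(u - rect_c[0]) / rect_f, (v - rect_c[1]) / rect_f, np.ones_like(u)], axis=-1)
    # rectified frame -> original camera frame
    d_orig = dirs @ r_cam  # (R_cam^T applied to each direction)
    xy = d_orig[..., :2] / d_orig[..., 2:3]
    if intr.has_distortion:
        xy = _distort_normalized(intr.distortion, xy)
    px = _denormalize(intr, xy)
    return px[..., 0], px[..., 1]


def _remap(image: np.ndarray, map_x: np.ndarray, map_y: np.ndarray, order: int) -> np.ndarray:
    coords = np.stack([map_y, map_x])
    if image.ndim == 2:
        out = map_coordinates(image.astype(float), coords, order=order, mode="nearest")
    else:
        out = np.stack(
            [
                map_coordinates(image[..., c].astype(float), coords, order=order, mode="nearest")
                for c in range(image.shape[2])
            ],
            axis=-1,
        )
    if np.issubdtype(image.dtype, np.integer):
        out = np.clip(np.round(out), np.iinfo(image.dtype).min, np.iinfo(image.dtype).max).astype(
            image.dtype
        )
    return out


def rectify_pair(raw: StereoFrame, rig: StereoRig, *, interpolation: str = "bilinear") -> StereoFrame:
    """Undistort and rectify a raw stereo pair.

    Each output pixel ray is rotated back into the original camera frame,
    forward-distorted, and sampled from the source image (inverse warping),
    so the result is simultaneously undistorted and row-aligned.
    """
    h, w = raw.image_shape
    if (w, h) != tuple(rig.left.image_size):
        raise DimensionMismatchError(
            f"image size {(w, h)} does not match rig image_size {rig.left.image_size}"
        )
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    r_l, r_r = rectifying_rotations(rig)
    cx1, cy = rig.rectified_left_principal
    f = rig.rectified_focal
    mx_l, my_l = _build_remap(rig.left, r_l, f, (cx1, cy), (w, h))
    mx_r, my_r = _build_remap(rig.right, r_r, f, (rig.rectified_right_principal_x, cy), (w, h))
    left = _remap(raw.left_image, mx_l, my_l, order)
    right = _remap(raw.right_image, mx_r, my_r, order)
    return StereoFrame(left, right, rectified=True, rig=rig)
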