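"""Dense disparity estimation from a rectified stereo pair.

Local block matching with a zero-normalized cross-correlation (ZNCC) cost,
winner-take-all selection, parabolic subpixel refinement, a uniqueness
test, a minimum-texture test and a left-right consistency check.  An
optional semi-global (4-path) aggregation smooths the cost volume before
selection.

Disparity follows the convention ``d = x_left - x_right >= 0`` for points
in front of the rig; invalid pixels carry NaN and are excluded from every
downstream statistic.  Failure modes are deliberate: textureless regions
fail the texture test (featureless tissue yields no matches) and pixels
visible in only one eye fail the left-right check, producing the gaps that
occluding instruments cut into the reconstructed surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .errors import NotRectifiedError
from .preprocess import StereoFrame

__all__ = ["DisparityParams", "DisparityMap", "compute_disparity"]

_EPS = 1e-12


@dataclass
class DisparityParams:
    """Block-matching parameters.

    ``uniqueness_ratio`` rejects a match when the best competing score
    (outside the +-1 px neighborhood of the winner) exceeds this fraction
    of the winning score.  ``texture_threshold`` is the minimum intensity
    standard deviation inside the matching block (8-bit units).
    """

    min_disparity: int = 0
    max_disparity: int = 64
    block_size: int = 9
    uniqueness_ratio: float = 0.95
    lr_max_diff: float = 1.0
    texture_threshold: float = 1.0
    min_score: float = 0.2
    semi_global: bool = False
    sgm_p1: float = 0.03
    sgm_p2: float = 0.5


@dataclass
class DisparityMap:
    """Subpixel disparity with validity mask; invalid pixels are NaN."""

    disparity: np.ndarray
    valid_mask: np.ndarray
    params: DisparityParams = field(default_factory=DisparityParams)

    def __post_init__(self) -> None:
        self.disparity = np.asarray(self.disparity, dtype=np.float32)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.disparity.shape != self.valid_mask.shape:
            raise ValueError("disparity and valid_mask shapes differ")
        self.disparity = self.disparity.copy()
        self.disparity[~self.valid_mask] = np.nan

    @property
    def shape(self) -> tuple[int, int]:
        return self.disparity.shape

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.valid_mask))


def _to_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 3:
        image = image.mean(axis=2)
    return image


def _box(img: np.ndarray, size: int) -> np.ndarray:
    return uniform_filter(img, size=size, mode="nearest")


def _zncc_volume(left: np.ndarray, right: np.ndarray, params: DisparityParams):
    """Score volume (H, W, D) of ZNCC between left blocks and right blocks
    shifted by each candidate disparity, plus the left block std map."""
    bs = params.block_size
    disparities = np.arange(params.min_disparity, params.max_disparity + 1)
    h, w = left.shape
    m_l = _box(left, bs)
    var_l = np.maximum(_box(left * left, bs) - m_l * m_l, 0.0)
    std_l = np.sqrt(var_l)
    m_r = _box(right, bs)
    var_r = np.maximum(_box(right * right, bs) - m_r * m_r, 0.0)
    std_r = np.sqrt(var_r)

    volume = np.full((h, w, len(disparities)), -np.inf, dtype=np.float32)
    for i, d in enumerate(disparities):
        if d >= w:
            continue
        if d > 0:
            prod = np.empty_like(left)
            prod[:, d:] = left[:, d:] * right[:, :-d]
            prod[:, :d] = 0.0
            cross = _box(prod, bs)[:, d:] - m_l[:, d:] * m_r[:, : w - d]
            denom = std_l[:, d:] * std_r[:, : w - d]
            volume[:, d:, i] = cross / np.maximum(denom, _EPS)
        else:
            cross = _box(left * right, bs) - m_l * m_r
            volume[:, :, i] = cross / np.maximum(std_l * std_r, _EPS)
    return volume, std_l, disparities


def _sgm_aggregate(volume: np.ndarray, p1: float, p2: float) -> np.ndarray:
    """4-path semi-global aggregation of a cost volume (lower = better)."""
    h, w, nd = volume.shape
    total = np.zeros_like(volume)
    big = np.float32(1e4)
    cost = np.where(np.isfinite(volume), volume, big).astype(np.float32)

    def scan(c: np.ndarray) -> np.ndarray:
        # aggregate along axis 1 (left to right); c is (A, B, D)
        out = np.empty_like(c)
        out[:, 0] = c[:, 0]
        for x in range(1, c.shape[1]):
            prev = out[:, x - 1]
            prev_min = prev.min(axis=-1, keepdims=True)
            shifted_p = np.empty_like(prev)
            shifted_m = np.empty_like(prev)
            shifted_p[:, 1:] = prev[:, :-1]
            shifted_p[:, 0] = big
            shifted_m[:, :-1] = prev[:, 1:]
            shifted_m[:, -1] = big
            best = np.minimum.reduce(
                [prev, shifted_p + p1, shifted_m + p1, np.broadcast_to(prev_min + p2, prev.shape)]
            )
            out[:, x] = c[:, x] + best - prev_min
        return out

    total += scan(cost)
    total += scan(cost[:, ::-1])[:, ::-1]
    swapped = cost.transpose(1, 0, 2)
    total += scan(swapped).transpose(1, 0, 2)
    total += scan(swapped[:, ::-1])[:, ::-1].transpose(1, 0, 2)
    return total


def _wta_subpixel(score: np.ndarray, disparities: np.ndarray):
    """Winner-take-all with 3-point parabolic refinement on the scores."""
    best_idx = np.argmax(score, axis=-1)
    h, w, nd = score.shape
    yy, xx = np.mgrid[0:h, 0:w]
    s0 = score[yy, xx, best_idx]
    lo = np.maximum(best_idx - 1, 0)
    hi = np.minimum(best_idx + 1, nd - 1)
    sm = score[yy, xx, lo]
    sp = score[yy, xx, hi]
    denom = sm - 2 * s0 + sp
    with np.errstate(divide="ignore", invalid="ignore"):
        offset = np.where(
            (best_idx > 0) & (best_idx < nd - 1) & (np.abs(denom) > _EPS),
            0.5 * (sm - sp) / denom,
            0.0,
        )
    offset = np.clip(offset, -0.5, 0.5)
    disp = disparities[best_idx] + offset
    return disp.astype(np.float32), best_idx, s0


def compute_disparity(frame: StereoFrame, params: DisparityParams | None = None) -> DisparityMap:
    """Compute the dense subpixel disparity map of a rectified pair."""
    if not frame.rectified:
        raise NotRectifiedError("compute_disparity requires a rectified StereoFrame")
    params = params or DisparityParams()
    h, w = frame.image_shape
    if not (0 <= params.min_disparity < params.max_disparity < w):
        raise ValueError(
            f"invalid disparity range [{params.min_disparity}, {params.max_disparity}] for width {w}"
        )
    if params.block_size < 3 or params.block_size % 2 == 0:
        raise ValueError("block size must be an odd integer >= 3")

    left = _to_gray(frame.left_image)
    right = _to_gray(frame.right_image)
    score, std_l, disparities = _zncc_volume(left, right, params)
    nd = len(disparities)

    if params.semi_global:
        cost = _sgm_aggregate(1.0 - score, params.sgm_p1, params.sgm_p2)
        disp, best_idx, _ = _wta_subpixel(-cost, disparities)
    else:
        disp, best_idx, _ = _wta_subpixel(score, disparities)

    yy, xx = np.mgrid[0:h, 0:w]
    best_score = score[yy, xx, best_idx]

    # uniqueness: best competitor outside +-1 of the winner
    masked = score.copy()
    for off in (-1, 0, 1):
        idx = np.clip(best_idx + off, 0, nd - 1)
        masked[yy, xx, idx] = -np.inf
    second = masked.max(axis=-1)
    unique_ok = ~(
        (second > 0) & (best_score > 0) & (second >= params.uniqueness_ratio * best_score)
    )

    valid = (
        np.isfinite(best_score)
        & (best_score >= params.min_score)
        & (std_l >= params.texture_threshold)
        & unique_ok
    )

    # exclude blocks that poke outside either image
    half = params.block_size // 2
    border = np.zeros((h, w), dtype=bool)
    border[half : h - half, half : w - half] = True
    valid &= border
    valid &= (xx - disp - half) >= 0

    # left-right consistency from the same score volume:
    # score_R(x_r, d) = score_L(x_r + d, d)
    score_r = np.full_like(score, -np.inf)
    for i, d in enumerate(disparities):
        if d == 0:
            score_r[:, :, i] = score[:, :, i]
        elif d < w:
            score_r[:, : w - d, i] = score[:, d:, i]
    disp_r, _, _ = _wta_subpixel(score_r, disparities)
    xr = np.clip(np.round(xx - disp).astype(int), 0, w - 1)
    lr_ok = np.abs(disp - disp_r[yy, xr]) <= params.lr_max_diff
    valid &= lr_ok

    disp_out = disp.copy()
    disp_out[~valid] = np.nan
    return DisparityMap(disp_out, valid, params)
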