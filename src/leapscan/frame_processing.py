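"""Subframe preparation: bit-depth conversion, cropping, alignment, integration.

The pipeline mirrors standard dose-fractionated SEM practice: raw 16-bit
signed subframes are shifted/rescaled to 8 bits, the distorted flyback margin
is cropped, a centred analysis region is taken, frames are registered by
patch-wise cross-correlation (5x5 patches, 20% overlap by default), averaged,
and optionally box-filtered before segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter
from skimage.registration import phase_cross_correlation

__all__ = [
    "ShiftTable",
    "convert_to_uint8",
    "crop_flyback",
    "center_crop",
    "align_frames",
    "integrate_frames",
    "mean_filter",
]


def convert_to_uint8(stack: np.ndarray) -> np.ndarray:
    """Rescale a signed 16-bit stack to uint8 using the stack-global min/max.

    ``out = round((v - min) * 255 / (max - min))``.  The min/max are taken over
    the whole stack, not per frame, so inter-frame intensity relations survive
    the conversion; a constant stack maps to 0.  The mapping is monotone
    non-decreasing, and idempotent (up to rounding) on full-range 8-bit data.
    """
    a = np.asarray(stack)
    if a.size == 0:
        raise ValueError("empty stack")
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        return np.zeros_like(a, dtype=np.uint8)
    return np.rint((a.astype(np.float64) - lo) * (255.0 / (hi - lo))).astype(np.uint8)


def crop_flyback(stack: np.ndarray, width_px: int = 64) -> np.ndarray:
    """Drop the leftmost ``width_px`` columns (the flyback-distorted margin)."""
    a = np.asarray(stack)
    nx = a.shape[-1]
    if not 0 <= width_px < nx:
        raise ValueError(f"width_px must satisfy 0 <= w < {nx}")
    return a[..., width_px:]


def center_crop(image_or_stack: np.ndarray, size: int) -> np.ndarray:
    """Centred square crop; odd margins are biased toward the top-left."""
    a = np.asarray(image_or_stack)
    ny, nx = a.shape[-2], a.shape[-1]
    if size > ny or size > nx:
        raise ValueError(f"crop size {size} exceeds image {ny}x{nx}")
    y0 = (ny - size) // 2
    x0 = (nx - size) // 2
    return a[..., y0:y0 + size, x0:x0 + size]


@dataclass
class ShiftTable:
    """Per-frame, per-patch (dy, dx) displacements and the patch geometry."""

    shifts: np.ndarray            # (R, gy, gx, 2) in pixels; frame 0 all zero
    centers_y: np.ndarray
    centers_x: np.ndarray
    patch_size: tuple[int, int]
    overlap_frac: float

    def rigid(self) -> np.ndarray:
        """Mean shift per frame — the whole-frame translation component."""
        return self.shifts.mean(axis=(1, 2))


def _patch_layout(n: int, g: int, overlap: float) -> tuple[np.ndarray, int]:
    base = n / g
    size = int(round(base * (1.0 + overlap)))
    size = min(size, n)
    centers = (np.arange(g) + 0.5) * base
    return centers, size


def align_frames(
    stack: np.ndarray,
    patch_grid: tuple[int, int] = (5, 5),
    overlap_frac: float = 0.20,
    max_shift: float | None = None,
    reference: str = "first",
    upsample: int = 10,
) -> tuple[np.ndarray, ShiftTable]:
    """Register frames to a reference by patch-wise cross-correlation.

    Each patch's translation is the cross-correlation peak against the
    reference (the first frame by default, or the running mean with
    ``reference='mean'``), found to 1/``upsample`` px and clipped to
    ``max_shift``.  Patch shifts are interpolated bilinearly to a per-pixel
    shift field and the frame resampled with reflection padding.  A 1x1 patch
    grid reduces to whole-frame rigid alignment.  The reference frame itself is
    never altered.
    """
    a = np.asarray(stack, dtype=np.float64)
    if a.ndim != 3 or a.shape[0] < 2:
        raise ValueError("need a stack of at least 2 frames")
    R, ny, nx = a.shape
    gy, gx = patch_grid
    cy, psy = _patch_layout(ny, gy, overlap_frac)
    cx, psx = _patch_layout(nx, gx, overlap_frac)
    if psy < 16 or psx < 16:
        raise ValueError(f"patches {psy}x{psx} smaller than 16 px; coarsen the grid")

    ref = a[0].copy()
    shifts = np.zeros((R, gy, gx, 2))
    aligned = np.empty_like(a)
    aligned[0] = a[0]
    Y, X = np.mgrid[0:ny, 0:nx].astype(np.float64)

    for r in range(1, R):
        for iy in range(gy):
            for ix in range(gx):
                y0 = int(np.clip(round(cy[iy] - psy / 2), 0, ny - psy))
                x0 = int(np.clip(round(cx[ix] - psx / 2), 0, nx - psx))
                sl = np.s_[y0:y0 + psy, x0:x0 + psx]
                sh, _, _ = phase_cross_correlation(ref[sl], a[r][sl],
                                                   upsample_factor=upsample,
                                                   normalization=None)
                if max_shift is not None:
                    sh = np.clip(sh, -max_shift, max_shift)
                shifts[r, iy, ix] = sh
        if gy == 1 and gx == 1:
            sy = np.full((ny, nx), shifts[r, 0, 0, 0])
            sx = np.full((ny, nx), shifts[r, 0, 0, 1])
        else:
            sy = _bilinear_field(shifts[r, :, :, 0], cy, cx, ny, nx)
            sx = _bilinear_field(shifts[r, :, :, 1], cy, cx, ny, nx)
        aligned[r] = map_coordinates(a[r], [Y - sy, X - sx], order=1, mode="reflect")
        if reference == "mean":
            ref = aligned[: r + 1].mean(axis=0)

    table = ShiftTable(shifts=shifts, centers_y=cy, centers_x=cx,
                       patch_size=(psy, psx), overlap_frac=overlap_frac)
    return aligned, table


def _bilinear_field(vals: np.ndarray, cy: np.ndarray, cx: np.ndarray,
                    ny: int, nx: int) -> np.ndarray:
    """Bilinear interpolation of patch-centre values to a full pixel grid."""
    yq = np.clip(np.arange(ny, dtype=np.float64), cy[0], cy[-1])
    xq = np.clip(np.arange(nx, dtype=np.float64), cx[0], cx[-1])
    iy = np.clip(np.searchsorted(cy, yq) - 1, 0, len(cy) - 2)
    ix = np.clip(np.searchsorted(cx, xq) - 1, 0, len(cx) - 2)
    wy = (yq - cy[iy]) / (cy[iy + 1] - cy[iy])
    wx = (xq - cx[ix]) / (cx[ix + 1] - cx[ix])
    v00 = vals[np.ix_(iy, ix)]
    v01 = vals[np.ix_(iy, ix + 1)]
    v10 = vals[np.ix_(iy + 1, ix)]
    v11 = vals[np.ix_(iy + 1, ix + 1)]
    wy = wy[:, None]
    wx = wx[None, :]
    return (v00 * (1 - wy) * (1 - wx) + v01 * (1 - wy) * wx
            + v10 * wy * (1 - wx) + v11 * wy * wx)


def integrate_frames(stack: np.ndarray, method: str = "mean") -> np.ndarray:
    """Pixel-wise reduction over frames; ``sum`` saturates at the dtype max."""
    a = np.asarray(stack)
    if a.ndim != 3 or a.shape[0] == 0:
        raise ValueError("need a non-empty 3D stack")
    if method == "mean":
        return a.mean(axis=0)
    if method == "sum":
        if np.issubdtype(a.dtype, np.integer):
            s = a.astype(np.int64).sum(axis=0)
            info = np.iinfo(a.dtype)
            if (s > info.max).any() or (s < info.min).any():
                warnings.warn("integrated sum saturates the input dtype; clipping",
                              RuntimeWarning, stacklevel=2)
            return np.clip(s, info.min, info.max).astype(a.dtype)
        return a.sum(axis=0)
    raise ValueError("method must be 'mean' or 'sum'")


def mean_filter(image: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Box mean with an odd kernel and reflective edge handling."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be odd and >= 1")
    a = np.asarray(image, dtype=np.float64)
    return uniform_filter(a, size=kernel, mode="reflect")
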