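"""Image-quality measures for charging assessment and segmentation scoring.

The central charging metric is the histogram mean of an 8-bit image: an
artefact-free, well-stretched image has its intensity population centred at
the 8-bit mid-range (127); accumulated charge manifests as extreme dark (or
bright) pixels that pull the mean away from it, so ``|mean - 127|`` serves as
a charging deviation score.  The module also estimates the spatial extent of
flyback distortions on the left image margin, scores segmentations by object
count and shape complexity (squared perimeter over area, summed), and
quantifies fast-axis streaking with a simple anisotropy index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import find_objects, gaussian_filter, sobel
from skimage.filters import threshold_minimum, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects

from .frame_processing import mean_filter

__all__ = [
    "QCReport",
    "FlybackEstimate",
    "histogram_mean",
    "estimate_flyback_extent",
    "segment_simple",
    "complexity_score",
    "normalize_to_reference",
    "anisotropy_index",
]

MID_RANGE = 127.0  # expected histogram centre of an artefact-free 8-bit image


@dataclass
class QCReport:
    """Per-image quality metrics keyed by acquisition condition."""

    condition: str
    histogram_mean: float = np.nan
    charging_deviation: float = np.nan
    anisotropy_index: float = np.nan
    flyback_extent_px: float | None = None
    n_objects: int = 0
    complexity_score: float = 0.0
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "histogram_mean": self.histogram_mean,
            "charging_deviation": self.charging_deviation,
            "anisotropy_index": self.anisotropy_index,
            "flyback_extent_px": self.flyback_extent_px,
            "n_objects": self.n_objects,
            "complexity_score": self.complexity_score,
        }


def histogram_mean(image: np.ndarray) -> tuple[float, float]:
    """Mean 8-bit intensity and its deviation from the 127 mid-range."""
    a = np.asarray(image)
    if a.size == 0:
        raise ValueError("empty image")
    if a.min() < 0 or a.max() > 255:
        raise ValueError("expected 8-bit-range intensities; convert first")
    m = float(a.mean())
    return m, abs(m - MID_RANGE)


@dataclass
class FlybackEstimate:
    """Aggregated flyback extent with per-frame values and failure diagnostics."""

    extent_px: float
    per_frame: list[float]
    n_failed: int
    warning: bool = False

    def __float__(self) -> float:
        return float(self.extent_px)


def estimate_flyback_extent(
    frames: np.ndarray,
    roi: tuple[int, int, int, int],
    sigma: float = 7.0,
    threshold_method: str | float = "minimum",
    aggregate: str = "median",
) -> FlybackEstimate:
    """Estimate how far flyback distortions extend from the left image edge.

    Per frame: Gaussian blur (``sigma`` = 7 px by default), 3x3 Sobel gradient
    magnitude, binarization by ``threshold_method`` (automatic histogram-valley
    ``'minimum'`` by default; ``'otsu'`` or a fixed value are accepted), then
    the rightmost column inside ``roi = (x, y, w, h)`` containing a foreground
    pixel.  Frames where thresholding or edge detection fails contribute
    nothing — real data shows such failures as histogram outliers — and the
    per-frame values are pooled by their median (mean by flag).  The Gaussian
    blur inherently extends the apparent edge by up to ~2*sigma.
    """
    a = np.asarray(frames, dtype=np.float64)
    if a.ndim == 2:
        a = a[None]
    x0, y0, w, h = roi
    ny, nx = a.shape[-2], a.shape[-1]
    if w <= 0 or h <= 0 or x0 < 0 or y0 < 0 or x0 + w > nx or y0 + h > ny:
        raise ValueError(f"roi {roi} outside {ny}x{nx} image")

    if isinstance(threshold_method, str) and threshold_method not in ("minimum", "otsu"):
        raise ValueError(f"unknown threshold method {threshold_method!r}")

    per_frame: list[float] = []
    failed = 0
    for frame in a:
        blurred = gaussian_filter(frame, sigma)
        grad = np.hypot(sobel(blurred, axis=0), sobel(blurred, axis=1))
        band = grad[y0:y0 + h, x0:x0 + w]
        try:
            if isinstance(threshold_method, (int, float)):
                thr = float(threshold_method)
            elif threshold_method == "minimum":
                thr = threshold_minimum(band)
            else:
                thr = threshold_otsu(band)
        except (RuntimeError, ValueError):
            failed += 1
            continue
        fg_cols = np.nonzero((band > thr).any(axis=0))[0]
        if fg_cols.size == 0:
            failed += 1
            continue
        per_frame.append(float(x0 + fg_cols[-1] + 1))

    if not per_frame:
        return FlybackEstimate(extent_px=0.0, per_frame=[], n_failed=failed, warning=True)
    pooled = float(np.median(per_frame) if aggregate == "median" else np.mean(per_frame))
    return FlybackEstimate(extent_px=pooled, per_frame=per_frame, n_failed=failed)


def segment_simple(image: np.ndarray, min_size: int = 20) -> np.ndarray:
    """Parameter-free fallback segmenter: 3x3 mean filter, automatic threshold,
    8-connected components, small components removed.  Labels run 1..N.

    This stands in for masks from any external segmenter; the downstream
    metrics consume only the integer label format.
    """
    a = np.asarray(image, dtype=np.float64)
    sm = mean_filter(a, 3)
    if np.ptp(sm) == 0:
        return np.zeros_like(a, dtype=np.int32)
    thr = threshold_otsu(sm)
    binary = sm > thr
    lab = cc_label(binary, connectivity=2)
    if min_size > 1:
        keep = remove_small_objects(lab > 0, max_size=min_size - 1)
        lab = cc_label(keep, connectivity=2)
    return lab.astype(np.int32)


def _crack_perimeter(mask: np.ndarray) -> int:
    """Boundary length as the count of foreground/background pixel edges."""
    padded = np.pad(mask.astype(np.int8), 1)
    return int(np.abs(np.diff(padded, axis=0)).sum()
               + np.abs(np.diff(padded, axis=1)).sum())


def complexity_score(label_mask: np.ndarray) -> tuple[int, float]:
    """Object count and summed shape complexity P^2/A over labelled components.

    The perimeter P is the crack-edge length (pixel-edge boundary count), which
    is exact for axis-aligned rectangles: a 10x10 square scores 40^2/100 = 16.
    A is the pixel count.  The score is additive over disjoint components and
    invariant under translation and integer upscaling of rectangles.
    """
    lab = np.asarray(label_mask)
    if (lab < 0).any():
        raise ValueError("label mask must be non-negative")
    labels = np.unique(lab)
    labels = labels[labels > 0]
    if labels.size == 0:
        return 0, 0.0
    total = 0.0
    slices = find_objects(lab)
    for lb in labels:
        sl = slices[lb - 1] if lb - 1 < len(slices) and slices[lb - 1] is not None else np.s_[:, :]
        m = lab[sl] == lb
        area = int(m.sum())
        per = _crack_perimeter(m)
        total += per ** 2 / area
    return int(labels.size), float(total)


def normalize_to_reference(metric_by_condition: dict[str, float],
                           reference_condition: str) -> dict[str, float]:
    """Divide each condition's metric by the reference condition's value."""
    if reference_condition not in metric_by_condition:
        raise KeyError(f"reference condition {reference_condition!r} missing")
    ref = metric_by_condition[reference_condition]
    if ref == 0:
        raise ZeroDivisionError("reference metric is zero")
    return {k: v / ref for k, v in metric_by_condition.items()}


def anisotropy_index(image: np.ndarray) -> float:
    """Texture anisotropy: mean |vertical difference| / mean |horizontal difference|.

    ~1 for isotropic texture; > 1 when intensity varies more across rows than
    along them, i.e. horizontal (fast-axis) streaking.  Transposition inverts
    the index.
    """
    a = np.asarray(image, dtype=np.float64)
    if a.ndim != 2 or min(a.shape) < 2:
        raise ValueError("need a 2D image with both dimensions >= 2")
    dv = np.abs(np.diff(a, axis=0)).mean()
    dh = np.abs(np.diff(a, axis=1)).mean()
    if dh == 0:
        return np.inf
    return float(dv / dh)
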