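"""Shared image preparation: ROI cropping, grayscale conversion, resizing, quantization.

Every feature extractor in the benchmark consumes images that pass through
these primitives, so their conventions (0-based half-open rectangles,
BT.601 luma, bilinear resizing without antialiasing, floor quantization)
are fixed here once and documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = ["RectROI", "crop_roi", "to_gray", "resize", "quantize_gray"]


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangle, 0-based, half-open: rows [top, top+height)."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError(f"ROI must be non-empty, got {self.height}x{self.width}")
        if self.top < 0 or self.left < 0:
            raise ValueError(f"ROI origin must be non-negative, got ({self.top}, {self.left})")


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB array, got shape {img.shape}")
    return img


def crop_roi(img: np.ndarray, roi: RectROI) -> np.ndarray:
    """Crop a rectangular region of interest out of an RGB image.

    The lens region is cropped manually upstream; this only extracts pixels,
    it never resamples. Raises ValueError naming the offending edge if the
    rectangle leaves the image.
    """
    img = _check_rgb(img)
    h, w = img.shape[:2]
    if roi.top + roi.height > h:
        raise ValueError(
            f"ROI bottom edge {roi.top + roi.height} exceeds image height {h}"
        )
    if roi.left + roi.width > w:
        raise ValueError(
            f"ROI right edge {roi.left + roi.width} exceeds image width {w}"
        )
    return img[roi.top : roi.top + roi.height, roi.left : roi.left + roi.width].copy()


def to_gray(img: np.ndarray) -> np.ndarray:
    """RGB -> 8-bit gray via ITU-R BT.601 luma (0.299 R + 0.587 G + 0.114 B)."""
    img = _check_rgb(img).astype(np.float64)
    gray = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def resize(img: np.ndarray, h: int, w: int) -> np.ndarray:
    """Bilinear resize to exactly (h, w), preserving dtype and value range.

    Antialiasing is deliberately off so the mapping is a pure bilinear
    interpolation — deterministic across backends and exact on constants.
    """
    if h < 1 or w < 1:
        raise ValueError(f"target size must be positive, got {h}x{w}")
    img = np.asarray(img)
    if img.shape[:2] == (h, w):
        return img.copy()
    lo, hi = img.min(), img.max()
    out = _sk_resize(
        img.astype(np.float64),
        (h, w) + img.shape[2:],
        order=1,
        anti_aliasing=False,
        preserve_range=True,
        mode="edge",
    )
    out = np.clip(out, lo, hi)  # bilinear cannot over/undershoot; guard fp noise
    if np.issubdtype(img.dtype, np.integer):
        return np.rint(out).astype(img.dtype)
    return out


def quantize_gray(img: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly quantize 8-bit gray values into ``levels`` bins: v -> floor(v*levels/256)."""
    if not 2 <= levels <= 256:
        raise ValueError(f"levels must be in [2, 256], got {levels}")
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D gray image, got shape {img.shape}")
    return (img.astype(np.int64) * levels // 256).astype(np.uint8)
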