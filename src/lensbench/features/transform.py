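"""Wavelet-coefficient and uniform-LBP image descriptors.

The wavelet descriptor is the full coefficient set of a two-level separable
2-D discrete wavelet decomposition of the resized gray image, flattened in
the fixed sub-band order LL2, LH2, HL2, HH2, LH1, HL1, HH1 (LH = horizontal
detail, HL = vertical detail). Periodization boundary handling keeps the
length deterministic (488 coefficients for a 15x30 image).

The LBP descriptor compares each pixel's eight 3x3 neighbors against the
center (neighbor order: east, then counter-clockwise), maps uniform codes
(at most two circular bit transitions) to their set-bit count 0..8 and all
non-uniform codes to the single label 9, then concatenates the 10-bin label
histograms of non-overlapping 9x9 windows. Pixels whose ring leaves the
window are skipped, so each 9x9 window contributes exactly its 7x7 = 49
interior pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from ..prep import resize
from .base import FeatureVector

__all__ = [
    "WaveletConfig",
    "LBPConfig",
    "dwt_feature_vector",
    "lbp_code",
    "uniformity",
    "lbp_value",
    "lbp_label_image",
    "lbp_feature_vector",
]

_SUPPORTED_WAVELETS = ("haar", "db1", "sym4")


@dataclass(frozen=True)
class WaveletConfig:
    wavelet_name: str = "haar"
    levels: int = 2
    target_size: tuple[int, int] = (15, 30)

    def __post_init__(self) -> None:
        if self.wavelet_name not in _SUPPORTED_WAVELETS:
            raise ValueError(
                f"wavelet {self.wavelet_name!r} not in supported set {_SUPPORTED_WAVELETS}"
            )
        if self.levels < 1:
            raise ValueError("levels must be >= 1")


@dataclass(frozen=True)
class LBPConfig:
    neighbors: int = 8
    radius: int = 1
    window: tuple[int, int] = (9, 9)
    target_size: tuple[int, int] = (20, 30)

    def __post_init__(self) -> None:
        if self.neighbors < 4:
            raise ValueError("neighbors must be >= 4")
        if self.window[0] > self.target_size[0] or self.window[1] > self.target_size[1]:
            raise ValueError(
                f"window {self.window} does not fit in target size {self.target_size}"
            )


def dwt_feature_vector(img: np.ndarray, cfg: WaveletConfig = WaveletConfig()) -> FeatureVector:
    """Flattened multi-level 2-D DWT coefficients of the resized gray image."""
    img = resize(np.asarray(img), *cfg.target_size).astype(np.float64)
    coeffs = pywt.wavedec2(img, cfg.wavelet_name, mode="periodization", level=cfg.levels)
    parts = [coeffs[0].ravel()]  # approximation band (LL at coarsest level)
    for level_bands in coeffs[1:]:  # coarsest -> finest; each is (LH, HL, HH)
        for band in level_bands:
            parts.append(band.ravel())
    values = np.concatenate(parts)
    return FeatureVector(
        values,
        {"wavelet": (0, len(values))},
        [f"wavelet_{k}" for k in range(len(values))],
    )


# 3x3 ring offsets (row, col): east, then counter-clockwise (rows grow downward)
_RING = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def lbp_code(patch: np.ndarray) -> int:
    """8-bit LBP code of a 3x3 patch: bit i set iff neighbor_i >= center."""
    patch = np.asarray(patch)
    if patch.shape != (3, 3):
        raise ValueError(f"expected 3x3 patch, got {patch.shape}")
    center = patch[1, 1]
    code = 0
    for bit, (dr, dc) in enumerate(_RING):
        if patch[1 + dr, 1 + dc] >= center:
            code |= 1 << bit
    return code


def uniformity(code: int, neighbors: int = 8) -> int:
    """Number of circular 0<->1 transitions in a P-bit code."""
    if not 0 <= code < (1 << neighbors):
        raise ValueError(f"code {code} out of range for {neighbors} bits")
    bits = [(code >> i) & 1 for i in range(neighbors)]
    return sum(bits[i] != bits[(i + 1) % neighbors] for i in range(neighbors))


def lbp_value(patch: np.ndarray, neighbors: int = 8) -> int:
    """Uniform-pattern label: set-bit count if uniform (U <= 2), else P+1."""
    code = lbp_code(patch)
    if uniformity(code, neighbors) <= 2:
        return int(bin(code).count("1"))
    return neighbors + 1


def lbp_label_image(img: np.ndarray) -> np.ndarray:
    """Uniform-LBP label (0..9) of every interior pixel, vectorized.

    Output shape is (H-2, W-2): border pixels have no complete 3x3 ring.
    """
    img = np.asarray(img).astype(np.int64)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"need a 2-D image of at least 3x3, got {img.shape}")
    center = img[1:-1, 1:-1]
    codes = np.zeros_like(center)
    for bit, (dr, dc) in enumerate(_RING):
        neighbor = img[1 + dr : img.shape[0] - 1 + dr, 1 + dc : img.shape[1] - 1 + dc]
        codes |= (neighbor >= center).astype(np.int64) << bit
    lut = np.array(
        [bin(c).count("1") if uniformity(c) <= 2 else 9 for c in range(256)],
        dtype=np.int64,
    )
    return lut[codes]


def lbp_feature_vector(img: np.ndarray, cfg: LBPConfig = LBPConfig()) -> FeatureVector:
    """Concatenated per-window uniform-LBP histograms of the resized image.

    The resized image is tiled by non-overlapping windows anchored at the
    top-left corner; partial windows at the right/bottom edges are dropped.
    For the 20x30 default this yields 2x3 windows x 10 labels = 60 features.
    """
    img = resize(np.asarray(img), *cfg.target_size)
    wh, ww = cfg.window
    n_rows = cfg.target_size[0] // wh
    n_cols = cfg.target_size[1] // ww
    n_labels = cfg.neighbors + 2
    histograms, names = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            window = img[r * wh : (r + 1) * wh, c * ww : (c + 1) * ww]
            labels = lbp_label_image(window)
            hist = np.bincount(labels.ravel(), minlength=n_labels).astype(np.float64)
            histograms.append(hist)
            names.extend([f"lbp_w{r}{c}_label{k}" for k in range(n_labels)])
    values = np.concatenate(histograms)
    return FeatureVector(values, {"lbp": (0, len(values))}, names)
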