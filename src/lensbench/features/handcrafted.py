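"""Color moments and co-occurrence texture descriptors (38-element vector).

Three blocks:

* 9 color moments — per RGB channel, the mean, the square root of the
  second central moment, and the signed cube root of the third central
  moment of the pixel intensities;
* 14 statistics of the direction-summed gray-tone spatial dependence
  matrix (GLCM, Haralick's canonical set);
* 15 statistics of the gray-gradient co-occurrence matrix (GGCM): the
  joint distribution of a pixel's quantized gray level and its quantized
  Sobel gradient magnitude.

All entropies use the natural logarithm with the convention 0·log 0 = 0.
Degenerate images (a single gray level, zero gradient everywhere) yield 0
for every correlation/entropy-type statistic rather than NaN; the exact
formulas are frozen in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..prep import quantize_gray, to_gray
from .base import FeatureVector

__all__ = [
    "CooccurrenceMatrix",
    "color_moments",
    "graytone_matrix",
    "graytone_features",
    "gradient_image",
    "disperse_gradient",
    "graygradient_matrix",
    "graygradient_features",
    "color_texture_vector",
    "GRAYTONE_NAMES",
    "GRAYGRADIENT_NAMES",
]

# (row, col) displacement per direction, rows increasing downward
_THETA_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GRAYTONE_NAMES = [
    "graytone_asm",
    "graytone_contrast",
    "graytone_correlation",
    "graytone_variance",
    "graytone_idm",
    "graytone_sum_average",
    "graytone_sum_variance",
    "graytone_sum_entropy",
    "graytone_entropy",
    "graytone_difference_variance",
    "graytone_difference_entropy",
    "graytone_imc1",
    "graytone_imc2",
    "graytone_max_corr_coeff",
]

GRAYGRADIENT_NAMES = [
    "graygradient_small_gradient_dominance",
    "graygradient_large_gradient_dominance",
    "graygradient_gray_asymmetry",
    "graygradient_gradient_asymmetry",
    "graygradient_energy",
    "graygradient_gray_mean",
    "graygradient_gradient_mean",
    "graygradient_gray_variance",
    "graygradient_gradient_variance",
    "graygradient_correlation",
    "graygradient_gray_entropy",
    "graygradient_gradient_entropy",
    "graygradient_mixed_entropy",
    "graygradient_inertia",
    "graygradient_idm",
]


@dataclass
class CooccurrenceMatrix:
    """Count matrix of co-occurring (gray, gray) or (gray, gradient) levels."""

    counts: np.ndarray
    kind: str  # "gray-tone" | "gray-gradient"
    d: int | None = None
    theta: int | None = None
    gradient_levels: int | None = None

    def probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("degenerate co-occurrence matrix with zero total count")
        return self.counts.astype(np.float64) / total


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def color_moments(img: np.ndarray) -> FeatureVector:
    """First three moments of each RGB channel, ordered [R, G, B] x [m1, m2, m3]."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got {img.shape}")
    values, names = [], []
    for c, channel in enumerate("RGB"):
        p = img[..., c].ravel()
        m1 = p.mean()
        centered = p - m1
        m2 = np.sqrt(np.mean(centered**2))
        m3 = np.cbrt(np.mean(centered**3))
        values.extend([m1, m2, m3])
        names.extend([f"color_{channel}_m{k}" for k in (1, 2, 3)])
    return FeatureVector(np.array(values), {"color": (0, 9)}, names)


def graytone_matrix(img: np.ndarray, d: int, theta: int, levels: int | None = None) -> CooccurrenceMatrix:
    """Gray-tone spatial dependence matrix at displacement (d, theta).

    ``img`` must already be quantized; pairs are counted symmetrically
    (both orderings), so the matrix is symmetric and the four-direction sum
    is free of direction asymmetry.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D quantized gray image, got {img.shape}")
    if d < 1:
        raise ValueError("displacement d must be >= 1")
    if theta not in _THETA_OFFSETS:
        raise ValueError(f"theta must be one of {sorted(_THETA_OFFSETS)}, got {theta}")
    levels = int(levels if levels is not None else img.max() + 1)
    dr, dc = (d * o for o in _THETA_OFFSETS[theta])
    h, w = img.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(
            f"no pixel pairs at displacement d={d}, theta={theta} in a {h}x{w} image"
        )
    a = img[r0:r1, c0:c1].astype(np.int64).ravel()
    b = img[r0 + dr : r1 + dr, c0 + dc : c1 + dc].astype(np.int64).ravel()
    flat = np.bincount(a * levels + b, minlength=levels * levels)
    counts = flat.reshape(levels, levels)
    counts = counts + counts.T  # symmetric counting: both orderings
    return CooccurrenceMatrix(counts, "gray-tone", d=d, theta=theta)


def _haralick_features(p: np.ndarray) -> np.ndarray:
    """Haralick's 14 statistics of a normalized, symmetric GLCM."""
    L = p.shape[0]
    i = np.arange(L, dtype=np.float64)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())
    ii, jj = np.meshgrid(i, i, indexing="ij")

    # p_{x+y}(k), k = 0..2L-2 and p_{|x-y|}(k), k = 0..L-1
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ii + jj).astype(int), p)
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), p)
    k_sum = np.arange(2 * L - 1, dtype=np.float64)
    k_diff = np.arange(L, dtype=np.float64)

    asm = (p**2).sum()
    contrast = (k_diff**2 * p_diff).sum()
    if sd_x > 0 and sd_y > 0:
        correlation = ((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 0.0
    variance = (((ii - mu_x) ** 2) * p).sum()
    idm = (p / (1.0 + (ii - jj) ** 2)).sum()
    sum_average = (k_sum * p_sum).sum()
    sum_variance = ((k_sum - sum_average) ** 2 * p_sum).sum()
    sum_entropy = -_xlogx(p_sum).sum()
    entropy = -_xlogx(p).sum()
    mu_diff = (k_diff * p_diff).sum()
    difference_variance = ((k_diff - mu_diff) ** 2 * p_diff).sum()
    difference_entropy = -_xlogx(p_diff).sum()

    hx = -_xlogx(px).sum()
    hy = -_xlogx(py).sum()
    pxpy = np.outer(px, py)
    mask = (p > 0) & (pxpy > 0)
    hxy1 = -(p[mask] * np.log(pxpy[mask])).sum()
    hxy2 = -_xlogx(pxpy).sum()
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy))))

    # maximal correlation coefficient: sqrt of the 2nd-largest eigenvalue of Q
    valid = px > 0
    if valid.sum() >= 2:
        pv = p[np.ix_(valid, valid)]
        q = (pv / px[valid, None]) @ (pv / py[valid][None, :]).T
        eigs = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
        mcc = float(np.sqrt(max(0.0, eigs[1])))
    else:
        mcc = 0.0

    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
            imc1,
            imc2,
            mcc,
        ]
    )


def graytone_features(img: np.ndarray, d: int = 1, levels: int = 16) -> FeatureVector:
    """The 14 Haralick statistics of the four-direction-summed GLCM.

    ``img`` is an 8-bit gray image; it is quantized to ``levels`` gray tones,
    the four directional matrices (0, 45, 90, 135 degrees) are summed and
    normalized, and the statistics are computed from the result.
    """
    q = quantize_gray(img, levels)
    total = np.zeros((levels, levels), dtype=np.int64)
    for theta in _THETA_OFFSETS:
        total += graytone_matrix(q, d, theta, levels=levels).counts
    p = total.astype(np.float64) / total.sum()
    return FeatureVector(_haralick_features(p), {"graytone": (0, 14)}, list(GRAYTONE_NAMES))


def gradient_image(img: np.ndarray) -> np.ndarray:
    """Sobel gradient-magnitude image (float), reflect boundary handling."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D gray image, got {img.shape}")
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"image {img.shape} too small for a 3x3 gradient operator")
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def disperse_gradient(grad: np.ndarray, levels: int) -> np.ndarray:
    """Linearly map gradient magnitudes onto integer levels 0..levels-1."""
    if levels < 2:
        raise ValueError("need at least 2 gradient levels")
    gmax = grad.max()
    if gmax == 0:
        return np.zeros(grad.shape, dtype=np.int64)
    return np.rint(grad / gmax * (levels - 1)).astype(np.int64)


def graygradient_matrix(
    img: np.ndarray, gradient_levels: int = 10, gray_levels: int = 16
) -> CooccurrenceMatrix:
    """Joint count matrix of (quantized gray level, quantized gradient level)."""
    gray = quantize_gray(img, gray_levels).astype(np.int64)
    grad = disperse_gradient(gradient_image(img), gradient_levels)
    flat = np.bincount(
        gray.ravel() * gradient_levels + grad.ravel(),
        minlength=gray_levels * gradient_levels,
    )
    counts = flat.reshape(gray_levels, gradient_levels)
    return CooccurrenceMatrix(counts, "gray-gradient", gradient_levels=gradient_levels)


def graygradient_features(
    img: np.ndarray, gradient_levels: int = 10, gray_levels: int = 16
) -> FeatureVector:
    """The 15 gray-gradient co-occurrence statistics."""
    p = graygradient_matrix(img, gradient_levels, gray_levels).probabilities()
    lg, ls = p.shape
    i = np.arange(lg, dtype=np.float64)  # gray level index
    j = np.arange(ls, dtype=np.float64)  # gradient level index
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    ii, jj = np.meshgrid(i, j, indexing="ij")

    mu_g = (i * pg).sum()
    mu_s = (j * ps).sum()
    var_g = ((i - mu_g) ** 2 * pg).sum()
    var_s = ((j - mu_s) ** 2 * ps).sum()
    if var_g > 0 and var_s > 0:
        corr = ((ii - mu_g) * (jj - mu_s) * p).sum() / np.sqrt(var_g * var_s)
    else:
        corr = 0.0

    values = np.array(
        [
            (ps / (j + 1.0) ** 2).sum(),
            (ps * j**2).sum(),
            (pg**2).sum(),
            (ps**2).sum(),
            (p**2).sum(),
            mu_g,
            mu_s,
            var_g,
            var_s,
            corr,
            -_xlogx(pg).sum(),
            -_xlogx(ps).sum(),
            -_xlogx(p).sum(),
            ((ii - jj) ** 2 * p).sum(),
            (p / (1.0 + (ii - jj) ** 2)).sum(),
        ]
    )
    return FeatureVector(values, {"graygradient": (0, 15)}, list(GRAYGRADIENT_NAMES))


def color_texture_vector(
    img: np.ndarray,
    d: int = 1,
    graytone_levels: int = 16,
    gradient_levels: int = 10,
    gray_levels: int = 16,
) -> FeatureVector:
    """Concatenated 38-element vector: [color 9 | gray-tone 14 | gray-gradient 15]."""
    gray = to_gray(img)
    return FeatureVector.concatenate(
        {
            "color": color_moments(img),
            "graytone": graytone_features(gray, d=d, levels=graytone_levels),
            "graygradient": graygradient_features(
                gray, gradient_levels=gradient_levels, gray_levels=gray_levels
            ),
        }
    )
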