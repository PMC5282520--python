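"""Independent brute-force oracles used by the test suite.

Every oracle here is deliberately written as plain loops / direct summation,
independent of the vectorized implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


def color_moments_loop(img: np.ndarray) -> list[float]:
    out = []
    h, w, _ = img.shape
    n = h * w
    for c in range(3):
        total = 0.0
        for i in range(h):
            for j in range(w):
                total += img[i, j, c]
        m1 = total / n
        s2 = s3 = 0.0
        for i in range(h):
            for j in range(w):
                d = img[i, j, c] - m1
                s2 += d * d
                s3 += d * d * d
        m2 = math.sqrt(s2 / n)
        m3c = s3 / n
        m3 = math.copysign(abs(m3c) ** (1.0 / 3.0), m3c)
        out.extend([m1, m2, m3])
    return out


_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_enumerate(img: np.ndarray, d: int, theta: int, levels: int) -> np.ndarray:
    """Count all in-bounds pixel pairs at (d, theta), both orderings."""
    h, w = img.shape
    dr, dc = (d * o for o in _OFFSETS[theta])
    counts = np.zeros((levels, levels), dtype=int)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[img[r, c], img[r2, c2]] += 1
                counts[img[r2, c2], img[r, c]] += 1
    return counts


def _entropy(values) -> float:
    return -sum(p * math.log(p) for p in values if p > 0)


def haralick_loop(p: np.ndarray) -> list[float]:
    """The 14 gray-tone statistics by direct summation over a normalized matrix."""
    L = p.shape[0]
    px = [sum(p[i, j] for j in range(L)) for i in range(L)]
    py = [sum(p[i, j] for i in range(L)) for j in range(L)]
    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(L)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(L)))
    p_sum = [0.0] * (2 * L - 1)
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]

    asm = sum(p[i, j] ** 2 for i in range(L) for j in range(L))
    contrast = sum(k * k * p_diff[k] for k in range(L))
    if sd_x > 0 and sd_y > 0:
        corr = (sum(i * j * p[i, j] for i in range(L) for j in range(L)) - mu_x * mu_y) / (
            sd_x * sd_y
        )
    else:
        corr = 0.0
    variance = sum((i - mu_x) ** 2 * p[i, j] for i in range(L) for j in range(L))
    idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    sum_avg = sum(k * p_sum[k] for k in range(2 * L - 1))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * L - 1))
    sum_ent = _entropy(p_sum)
    ent = _entropy(p.ravel())
    mu_d = sum(k * p_diff[k] for k in range(L))
    diff_var = sum((k - mu_d) ** 2 * p_diff[k] for k in range(L))
    diff_ent = _entropy(p_diff)
    hx, hy = _entropy(px), _entropy(py)
    hxy1 = -sum(
        p[i, j] * math.log(px[i] * py[j])
        for i in range(L)
        for j in range(L)
        if p[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = _entropy([px[i] * py[j] for i in range(L) for j in range(L)])
    denom = max(hx, hy)
    imc1 = (ent - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - ent))))
    valid = [i for i in range(L) if px[i] > 0]
    if len(valid) >= 2:
        q = np.zeros((len(valid), len(valid)))
        for a, i in enumerate(valid):
            for b, j in enumerate(valid):
                q[a, b] = sum(
                    p[i, k] * p[j, k] / (px[i] * py[k]) for k in valid if py[k] > 0
                )
        eigs = sorted(np.real(np.linalg.eigvals(q)), reverse=True)
        mcc = math.sqrt(max(0.0, eigs[1]))
    else:
        mcc = 0.0
    return [
        asm, contrast, corr, variance, idm, sum_avg, sum_var, sum_ent, ent,
        diff_var, diff_ent, imc1, imc2, mcc,
    ]


def sobel_loop(img: np.ndarray) -> np.ndarray:
    """Sobel magnitude with explicit 3x3 kernels and reflect padding."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    ky = kx.T
    h, w = img.shape
    padded = np.pad(img.astype(float), 1, mode="symmetric")  # ndimage 'reflect'
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            win = padded[r : r + 3, c : c + 3]
            gx = (win * kx[::-1, ::-1]).sum()  # convolution flips the kernel
            gy = (win * ky[::-1, ::-1]).sum()
            out[r, c] = math.hypot(gx, gy)
    return out


def ggcm_loop(gray_q: np.ndarray, grad_q: np.ndarray, lg: int, ls: int) -> list[float]:
    """The 15 gray-gradient statistics from quantized gray + gradient images."""
    H = np.zeros((lg, ls))
    h, w = gray_q.shape
    for r in range(h):
        for c in range(w):
            H[gray_q[r, c], grad_q[r, c]] += 1
    p = H / H.sum()
    pg = [sum(p[i, j] for j in range(ls)) for i in range(lg)]
    ps = [sum(p[i, j] for i in range(lg)) for j in range(ls)]
    mu_g = sum(i * pg[i] for i in range(lg))
    mu_s = sum(j * ps[j] for j in range(ls))
    var_g = sum((i - mu_g) ** 2 * pg[i] for i in range(lg))
    var_s = sum((j - mu_s) ** 2 * ps[j] for j in range(ls))
    if var_g > 0 and var_s > 0:
        corr = sum(
            (i - mu_g) * (j - mu_s) * p[i, j] for i in range(lg) for j in range(ls)
        ) / math.sqrt(var_g * var_s)
    else:
        corr = 0.0
    return [
        sum(ps[j] / (j + 1) ** 2 for j in range(ls)),
        sum(ps[j] * j * j for j in range(ls)),
        sum(v * v for v in pg),
        sum(v * v for v in ps),
        sum(p[i, j] ** 2 for i in range(lg) for j in range(ls)),
        mu_g,
        mu_s,
        var_g,
        var_s,
        corr,
        _entropy(pg),
        _entropy(ps),
        _entropy(p.ravel()),
        sum((i - j) ** 2 * p[i, j] for i in range(lg) for j in range(ls)),
        sum(p[i, j] / (1 + (i - j) ** 2) for i in range(lg) for j in range(ls)),
    ]


def haar_step_2d(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One orthonormal 2-D haar analysis step via explicit 2x2 averages/differences."""
    h, w = img.shape
    assert h % 2 == 0 and w % 2 == 0
    ll = np.zeros((h // 2, w // 2))
    lh = np.zeros_like(ll)
    hl = np.zeros_like(ll)
    hh = np.zeros_like(ll)
    for r in range(0, h, 2):
        for c in range(0, w, 2):
            a, b = img[r, c], img[r, c + 1]
            cc, d = img[r + 1, c], img[r + 1, c + 1]
            ll[r // 2, c // 2] = (a + b + cc + d) / 2
            lh[r // 2, c // 2] = (a - b + cc - d) / 2  # left minus right
            hl[r // 2, c // 2] = (a + b - cc - d) / 2  # top minus bottom
            hh[r // 2, c // 2] = (a - b - cc + d) / 2
    return ll, lh, hl, hh


def lbp_code_bits(patch: np.ndarray) -> int:
    ring = [(1, 2), (0, 2), (0, 1), (0, 0), (1, 0), (2, 0), (2, 1), (2, 2)]
    code = 0
    for bit, (r, c) in enumerate(ring):
        if patch[r, c] >= patch[1, 1]:
            code += 2**bit
    return code


def auc_pairwise(labels: np.ndarray, scores: np.ndarray) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def knn_bruteforce(train_X, train_y, query, k) -> tuple[int, float]:
    dists = [
        (math.sqrt(((query - x) ** 2).sum()), i) for i, x in enumerate(train_X)
    ]
    dists.sort()
    votes = [train_y[i] for _, i in dists[:k]]
    frac = sum(votes) / k
    return (1 if frac > 0.5 else 0), frac
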