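"""Independent brute-force oracles used to validate the vectorized code.

Everything here is written as explicit per-element loops over the documented
definitions, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# LBP
# ---------------------------------------------------------------------------

def lbp_code_oracle(image: np.ndarray, pixel, size: int, bits: int = 8) -> np.ndarray:
    """Per-neighbor comparison loop: bit = 1 when neighbor >= center."""
    img = np.asarray(image, dtype=float)
    radius = (size - 1) / 2.0
    pad = int(math.ceil(radius)) + 1
    p = np.pad(img, pad, mode="reflect")
    r0, c0 = pixel[0] + pad, pixel[1] + pad
    center = p[r0, c0]
    code = np.zeros(bits)
    for b in range(bits):
        ang = 2.0 * math.pi * b / bits
        rr = r0 - radius * math.sin(ang)
        cc = c0 + radius * math.cos(ang)
        fr, fc = rr - math.floor(rr), cc - math.floor(cc)
        if fr < 1e-9:
            fr = 0.0
        if fc < 1e-9:
            fc = 0.0
        i, j = int(math.floor(rr)), int(math.floor(cc))
        val = (
            p[i, j] * (1 - fr) * (1 - fc)
            + p[i, j + 1] * (1 - fr) * fc
            + p[i + 1, j] * fr * (1 - fc)
            + p[i + 1, j + 1] * fr * fc
        )
        code[b] = 1.0 if (val - center) >= -1e-8 * (1.0 + abs(center)) else 0.0
    return code


# ---------------------------------------------------------------------------
# Gabor
# ---------------------------------------------------------------------------

def gabor_response_oracle(image: np.ndarray, pixel, size: int,
                          angle_deg: float) -> float:
    """Direct spatial-domain correlation sum at one pixel, explicit loops."""
    img = np.asarray(image, dtype=float)
    r = (size - 1) // 2
    lam = float(size)
    sigma = 0.5 * lam
    theta = math.radians(angle_deg)
    kern = np.empty((size, size), dtype=complex)
    for yy in range(-r, r + 1):
        for xx in range(-r, r + 1):
            u = xx * math.cos(theta) + yy * math.sin(theta)
            env = math.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
            kern[yy + r, xx + r] = env * complex(
                math.cos(2 * math.pi * u / lam), math.sin(2 * math.pi * u / lam)
            )
    kern = kern - kern.mean()
    p = np.pad(img, r, mode="reflect")
    acc = 0.0 + 0.0j
    for yy in range(-r, r + 1):
        for xx in range(-r, r + 1):
            acc += p[pixel[0] + r + yy, pixel[1] + r + xx] * kern[yy + r, xx + r]
    return abs(acc)


# ---------------------------------------------------------------------------
# Haralick
# ---------------------------------------------------------------------------

def quantize_window_oracle(window: np.ndarray, gray_levels: int) -> np.ndarray:
    w = np.asarray(window, dtype=float)
    mn, mx = w.min(), w.max()
    span = mx - mn if mx > mn else 1.0
    q = np.empty(w.shape, dtype=int)
    for i in range(w.shape[0]):
        for j in range(w.shape[1]):
            q[i, j] = min(int((w[i, j] - mn) / span * gray_levels), gray_levels - 1)
    return q


def glcm_oracle(q: np.ndarray, gray_levels: int, offset) -> np.ndarray:
    """Explicit pair-counting loop; symmetric, normalized."""
    k = q.shape[0]
    dr, dc = offset
    counts = np.zeros((gray_levels, gray_levels))
    for i in range(k):
        for j in range(k):
            ii, jj = i + dr, j + dc
            if 0 <= ii < k and 0 <= jj < k:
                counts[q[i, j], q[ii, jj]] += 1
                counts[q[ii, jj], q[i, j]] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def haralick_stats_oracle(p: np.ndarray) -> np.ndarray:
    """Scalar-loop version of the 14 statistics (natural logs)."""
    L = p.shape[0]
    px = [sum(p[i, j] for j in range(L)) for i in range(L)]
    py = [sum(p[i, j] for i in range(L)) for j in range(L)]
    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(L))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(L))
    p_sum = [0.0] * (2 * L - 1)
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]

    def ln(x):
        return math.log(x) if x > 1e-12 else 0.0

    f = np.zeros(14)
    f[0] = sum(p[i, j] ** 2 for i in range(L) for j in range(L))
    f[1] = sum(d * d * p_diff[d] for d in range(L))
    sig = math.sqrt(max(var_x * var_y, 0.0))
    cov = sum(i * j * p[i, j] for i in range(L) for j in range(L)) - mu_x * mu_y
    f[2] = cov / sig if sig > 1e-12 else 0.0
    f[3] = var_x
    f[4] = sum(p[i, j] / (1.0 + (i - j) ** 2) for i in range(L) for j in range(L))
    f[5] = sum(s * p_sum[s] for s in range(2 * L - 1))
    f[6] = sum((s - f[5]) ** 2 * p_sum[s] for s in range(2 * L - 1))
    f[7] = -sum(p_sum[s] * ln(p_sum[s]) for s in range(2 * L - 1))
    f[8] = -sum(p[i, j] * ln(p[i, j]) for i in range(L) for j in range(L))
    mu_d = sum(d * p_diff[d] for d in range(L))
    f[9] = sum((d - mu_d) ** 2 * p_diff[d] for d in range(L))
    f[10] = -sum(p_diff[d] * ln(p_diff[d]) for d in range(L))
    hxy1 = -sum(p[i, j] * ln(px[i] * py[j]) for i in range(L) for j in range(L))
    hxy2 = -sum(px[i] * py[j] * ln(px[i] * py[j]) for i in range(L) for j in range(L))
    hx = -sum(px[i] * ln(px[i]) for i in range(L))
    hy = -sum(py[j] * ln(py[j]) for j in range(L))
    hmax = max(hx, hy)
    f[11] = (f[8] - hxy1) / hmax if hmax > 1e-12 else 0.0
    f[12] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * max(hxy2 - f[8], 0.0))))
    # maximal correlation coefficient via the explicitly built Q matrix
    occupied = [i for i in range(L) if px[i] > 1e-12]
    if len(occupied) < 2:
        f[13] = 0.0
    else:
        Q = np.zeros((len(occupied), len(occupied)))
        for a, i in enumerate(occupied):
            for b, j in enumerate(occupied):
                Q[a, b] = sum(
                    p[i, k] * p[j, k] / (px[i] * py[k])
                    for k in range(L) if py[k] > 1e-12
                )
        eigs = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
        f[13] = math.sqrt(min(max(eigs[1], 0.0), 1.0))
    return f


def haralick_descriptor_oracle(image: np.ndarray, pixel, size: int,
                               gray_levels: int = 32) -> np.ndarray:
    """Offset-averaged 14 statistics of the window centred at ``pixel``."""
    img = np.asarray(image, dtype=float)
    r = (size - 1) // 2
    p = np.pad(img, r, mode="reflect")
    window = p[pixel[0] : pixel[0] + size, pixel[1] : pixel[1] + size]
    q = quantize_window_oracle(window, gray_levels)
    offsets = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
    acc = np.zeros(14)
    for off in offsets:
        acc += haralick_stats_oracle(glcm_oracle(q, gray_levels, off))
    return acc / len(offsets)


# ---------------------------------------------------------------------------
# dense SIFT / PHOW
# ---------------------------------------------------------------------------

def phow_descriptor_oracle(image: np.ndarray, pixel, size: int,
                           pad: int) -> np.ndarray:
    """Explicit-loop dense-SIFT descriptor (4x4 spatial bins, 8 orientations).

    ``pad`` must match the reflect padding the implementation applied for
    its scale grid, so gradient values coincide exactly.
    """
    img = np.pad(np.asarray(image, dtype=float), pad, mode="reflect")
    m = int(math.ceil(size / 4))
    h, w = img.shape
    gy = np.zeros_like(img)
    gx = np.zeros_like(img)
    for i in range(h):
        for j in range(w):
            gy[i, j] = (
                img[min(i + 1, h - 1), j] - img[max(i - 1, 0), j]
            ) / (2.0 if 0 < i < h - 1 else 1.0)
            gx[i, j] = (
                img[i, min(j + 1, w - 1)] - img[i, max(j - 1, 0)]
            ) / (2.0 if 0 < j < w - 1 else 1.0)

    def channel_value(o, i, j):
        mag = math.hypot(gx[i, j], gy[i, j])
        ang = math.atan2(gy[i, j], gx[i, j]) % (2 * math.pi)
        pos = ang / (2 * math.pi) * 8.0
        lo = int(math.floor(pos)) % 8
        hi = (lo + 1) % 8
        w_hi = pos - math.floor(pos)
        if o == lo and o == hi:
            return mag
        if o == lo:
            return mag * (1.0 - w_hi)
        if o == hi:
            return mag * w_hi
        return 0.0

    def box_mean(o, ci, cj):
        # scipy uniform_filter window for size m: offsets -(m//2) .. m-1-m//2
        vals = [
            channel_value(o, ci + di, cj + dj)
            for di in range(-(m // 2), m - m // 2)
            for dj in range(-(m // 2), m - m // 2)
        ]
        return sum(vals) / len(vals)

    r0, c0 = pixel[0] + pad, pixel[1] + pad
    desc = np.zeros((4, 4, 8))
    for bi in range(4):
        for bj in range(4):
            dr = int(round((bi - 1.5) * m))
            dc = int(round((bj - 1.5) * m))
            for o in range(8):
                desc[bi, bj, o] = box_mean(o, r0 + dr, c0 + dc)
    v = desc.ravel()
    n = np.linalg.norm(v)
    return v / n if n > 1e-10 else np.zeros(128)


# ---------------------------------------------------------------------------
# optimizer oracles
# ---------------------------------------------------------------------------

def nonneg_qp_enumeration_oracle(Q: np.ndarray, c: np.ndarray):
    """Exhaustive active-set enumeration for min 0.5 w'Qw + c'w, w >= 0."""
    S = len(c)
    best_val, best_w = 0.0, np.zeros(S)  # w = 0 is always admissible
    for r in range(1, S + 1):
        for F in itertools.combinations(range(S), r):
            F = list(F)
            w = np.zeros(S)
            try:
                w[F] = np.linalg.solve(Q[np.ix_(F, F)], -c[F])
            except np.linalg.LinAlgError:
                continue
            if np.any(w[F] < 0):
                continue
            val = 0.5 * w @ Q @ w + c @ w
            if val < best_val:
                best_val, best_w = val, w
    return best_w, best_val


def snnls_objective(kernels, a, w, alpha, eta) -> float:
    """The w-subproblem objective evaluated directly."""
    z = np.linalg.solve(kernels.R_p, a)  # R_p upper triangular
    resid = kernels.H_b.T @ z - kernels.H_b.T @ w
    return float(resid @ resid + alpha * w @ w + eta * np.sum(np.abs(w)))


def a_update_oracle(S_p_ridged: np.ndarray, S_b: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Direct evaluation of the closed-form a-step via matrix inverses."""
    R = np.linalg.cholesky(S_p_ridged).T  # upper triangular
    num = np.linalg.inv(R.T) @ (S_b @ w)
    den = math.sqrt(float(w @ S_b @ S_b @ w))
    return num / den


# ---------------------------------------------------------------------------
# smoothing oracle
# ---------------------------------------------------------------------------

def superpixel_mode_oracle(quantized: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-region modal level with ties toward the smaller level."""
    out = np.empty_like(quantized, dtype=float)
    for lab in np.unique(labels):
        sel = labels == lab
        vals = np.round(quantized[sel], 1)
        levels, counts = np.unique(vals, return_counts=True)
        out[sel] = levels[np.argmax(counts)]  # unique() sorts ascending
    return out
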