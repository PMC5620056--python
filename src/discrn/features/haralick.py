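"""Multi-scale Haralick statistics of per-window gray-level co-occurrence.

For each pixel and window size ``k`` the ``k x k`` neighborhood is min-max
quantized to ``gray_levels`` levels, a symmetric normalized co-occurrence
matrix (GLCM) is accumulated for each of the four distance-1 offsets
(0, 45, 90, 135 degrees), the 14 classic statistics are computed per offset,
and the statistics are averaged over offsets.  Varying ``k`` yields the
multi-scale family.

Degenerate cases follow fixed conventions rather than producing NaN: windows
with a single gray level quantize to level 0 (GLCM mass on one diagonal
cell), correlation-type statistics (f3, f12, f14) are 0 when their
denominators vanish, and entropies use ``log(p)`` only over ``p > 0``.

The implementation is vectorized over windows (bincount-based GLCM
accumulation, batched matmuls and symmetric eigendecompositions), since a
per-pixel Python loop is far too slow for exhaustive image labeling.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..types import Family, MultiScaleFeatureSet, ScaleGrid
from ._util import as_gray_float, check_pixels, check_scales_fit, pad_reflect

N_STATISTICS = 14

#: distance-1 offsets (row, col) for 0, 45, 90 and 135 degrees
OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_EPS = 1e-12


def quantize_windows(windows: np.ndarray, gray_levels: int) -> np.ndarray:
    """Min-max quantize each window to integer levels 0..gray_levels-1."""
    mn = windows.min(axis=(1, 2), keepdims=True)
    mx = windows.max(axis=(1, 2), keepdims=True)
    span = mx - mn
    span = np.where(span <= 0, 1.0, span)
    q = np.floor((windows - mn) / span * gray_levels).astype(np.intp)
    return np.minimum(q, gray_levels - 1)


def glcm_per_offset(q: np.ndarray, gray_levels: int, offset) -> np.ndarray:
    """Symmetric normalized GLCM per window for one (drow, dcol) offset.

    ``q``: (n, k, k) integer level windows.  Returns (n, L, L) with each
    matrix summing to 1 (windows too small for the offset would sum to 0,
    but k >= 3 always admits distance-1 pairs).
    """
    n, k, _ = q.shape
    L = gray_levels
    dr, dc = offset
    r0, r1 = max(0, -dr), min(k, k - dr)
    c0, c1 = max(0, -dc), min(k, k - dc)
    a = q[:, r0:r1, c0:c1].reshape(n, -1)
    b = q[:, r0 + dr : r1 + dr, c0 + dc : c1 + dc].reshape(n, -1)
    win = np.repeat(np.arange(n, dtype=np.intp), a.shape[1])
    idx = win * (L * L) + a.ravel() * L + b.ravel()
    counts = np.bincount(idx, minlength=n * L * L).reshape(n, L, L)
    counts = counts + counts.transpose(0, 2, 1)  # symmetrize
    total = counts.sum(axis=(1, 2), keepdims=True).astype(np.float64)
    total = np.where(total <= 0, 1.0, total)
    return counts / total


def haralick_statistics(p: np.ndarray) -> np.ndarray:
    """The 14 Haralick statistics of a batch of normalized GLCMs.

    ``p``: (n, L, L), each summing to 1 (symmetric).  Returns (n, 14).
    Order: ASM, contrast, correlation, sum-of-squares variance, inverse
    difference moment, sum average, sum variance, sum entropy, entropy,
    difference variance, difference entropy, info. measure of correlation 1
    and 2, maximal correlation coefficient.  Natural logarithms throughout.
    """
    n, L, _ = p.shape
    i = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=2)  # (n, L); == py by symmetry
    py = p.sum(axis=1)
    mu_x = px @ i
    mu_y = py @ i
    var_x = px @ (i**2) - mu_x**2
    var_y = py @ (i**2) - mu_y**2

    flat = p.reshape(n, L * L)
    # p_{x+y}(s), s = 0..2L-2 and p_{|x-y|}(d), d = 0..L-1
    sum_idx = (ii + jj).astype(np.intp).ravel()
    diff_idx = np.abs(ii - jj).astype(np.intp).ravel()
    sum_onehot = np.zeros((L * L, 2 * L - 1))
    sum_onehot[np.arange(L * L), sum_idx] = 1.0
    diff_onehot = np.zeros((L * L, L))
    diff_onehot[np.arange(L * L), diff_idx] = 1.0
    p_sum = flat @ sum_onehot
    p_diff = flat @ diff_onehot
    s_vals = np.arange(2 * L - 1, dtype=np.float64)
    d_vals = i

    def nlog(x):
        return np.where(x > _EPS, np.log(np.maximum(x, _EPS)), 0.0)

    f = np.empty((n, N_STATISTICS), dtype=np.float64)
    f[:, 0] = np.einsum("nij,nij->n", p, p)  # ASM / energy
    f[:, 1] = p_diff @ (d_vals**2)  # contrast
    sig = np.sqrt(np.maximum(var_x * var_y, 0.0))
    cov = np.einsum("nij,ij->n", p, ii * jj) - mu_x * mu_y
    f[:, 2] = np.where(sig > _EPS, cov / np.maximum(sig, _EPS), 0.0)
    f[:, 3] = var_x  # sum of squares: variance, equals sum_ij (i - mu_x)^2 p_ij
    f[:, 4] = np.einsum("nij,ij->n", p, 1.0 / (1.0 + (ii - jj) ** 2))  # IDM
    f6 = p_sum @ s_vals
    f[:, 5] = f6  # sum average
    f[:, 6] = np.einsum("ns,ns->n", p_sum, (s_vals[None, :] - f6[:, None]) ** 2)  # sum variance
    f[:, 7] = -np.einsum("ns,ns->n", p_sum, nlog(p_sum))  # sum entropy
    hxy = -np.einsum("nij,nij->n", p, nlog(p))
    f[:, 8] = hxy  # entropy
    mu_d = p_diff @ d_vals
    f[:, 9] = np.einsum("nd,nd->n", p_diff, (d_vals[None, :] - mu_d[:, None]) ** 2)  # difference variance
    f[:, 10] = -np.einsum("nd,nd->n", p_diff, nlog(p_diff))  # difference entropy

    pxpy = px[:, :, None] * py[:, None, :]
    hxy1 = -np.einsum("nij,nij->n", p, nlog(pxpy))
    hxy2 = -np.einsum("nij,nij->n", pxpy, nlog(pxpy))
    hx = -np.einsum("ni,ni->n", px, nlog(px))
    hy = -np.einsum("ni,ni->n", py, nlog(py))
    hmax = np.maximum(hx, hy)
    f[:, 11] = np.where(hmax > _EPS, (hxy - hxy1) / np.maximum(hmax, _EPS), 0.0)
    f[:, 12] = np.sqrt(np.maximum(0.0, 1.0 - np.exp(-2.0 * np.maximum(hxy2 - hxy, 0.0))))
    f[:, 13] = _max_correlation_coeff(p, px, py)
    return f


def _max_correlation_coeff(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """sqrt of the second largest eigenvalue of Q_ij = sum_k p_ik p_jk / (px_i py_k).

    Q is similar to M M^T with M = Dx^{-1/2} P Dy^{-1/2}, which is symmetric
    PSD, so a batched ``eigvalsh`` suffices.  Windows with fewer than two
    occupied levels get the documented fallback value 0.
    """
    n, L, _ = p.shape
    sx = np.where(px > _EPS, 1.0 / np.sqrt(np.maximum(px, _EPS)), 0.0)
    sy = np.where(py > _EPS, 1.0 / np.sqrt(np.maximum(py, _EPS)), 0.0)
    m = p * sx[:, :, None] * sy[:, None, :]
    b = m @ m.transpose(0, 2, 1)
    eig = np.linalg.eigvalsh(b)  # ascending
    second = np.clip(eig[:, -2], 0.0, 1.0)
    occupied = (px > _EPS).sum(axis=1)
    return np.where(occupied >= 2, np.sqrt(second), 0.0)


def extract_haralick(
    image: np.ndarray,
    pixels,
    scales: ScaleGrid,
    gray_levels: int = 32,
    slice_id: int = 0,
) -> MultiScaleFeatureSet:
    """14 Haralick statistics per pixel per scale (offset-averaged)."""
    if gray_levels < 2:
        raise ValueError("gray_levels must be >= 2")
    img = as_gray_float(image)
    check_scales_fit(img.shape, scales)
    px = check_pixels(img.shape, pixels)
    pad = scales.max_radius
    padded = pad_reflect(img, pad)

    out = np.empty((len(px), len(scales), N_STATISTICS), dtype=np.float64)
    for si, size in enumerate(scales.sizes):
        r = (size - 1) // 2
        wins = sliding_window_view(padded, (size, size))
        wins = wins[px[:, 0] + pad - r, px[:, 1] + pad - r]
        q = quantize_windows(np.ascontiguousarray(wins), gray_levels)
        acc = np.zeros((len(px), N_STATISTICS))
        for offset in OFFSETS:
            p = glcm_per_offset(q, gray_levels, offset)
            acc += haralick_statistics(p)
        out[:, si, :] = acc / len(OFFSETS)
    return MultiScaleFeatureSet(
        family=Family.HARALICK,
        scales=scales,
        descriptors=out,
        pixel_coords=px,
        slice_ids=np.full(len(px), slice_id, dtype=np.intp),
    )
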