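"""Multi-scale Local Binary Patterns with circular neighbor sampling.

For a window of side ``k`` the neighbor circle has radius ``(k - 1) / 2``.
``bits`` neighbors are placed equally spaced on that circle, their intensities
obtained by bilinear interpolation, and bit ``b`` is set to 1 when the
neighbor intensity is >= the center intensity (ties resolve to 1).  Codes are
therefore invariant to adding a constant to the whole image.

The descriptor is the raw bit vector (not the packed integer), so that the
Hamming distance between two codes is a plain sum of absolute bit
differences.  An optional rotation-invariant mapping replaces each code by
the lexicographically smallest of its cyclic rotations.
"""

from __future__ import annotations

import numpy as np

from ..types import Family, MultiScaleFeatureSet, ScaleGrid
from ._util import as_gray_float, check_pixels, check_scales_fit, pad_reflect

# Comparison tolerance: bilinear weights are computed in floating point, so a
# constant intensity shift can perturb interpolated values by ~1e-16 * shift.
_TOL = 1e-8


def _bilinear(padded: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear interpolation at fractional (row, col) positions."""
    r0 = np.floor(rows).astype(np.intp)
    c0 = np.floor(cols).astype(np.intp)
    fr = rows - r0
    fc = cols - c0
    # snap near-integer offsets so axis-aligned neighbors are sampled exactly
    fr = np.where(fr < 1e-9, 0.0, fr)
    fc = np.where(fc < 1e-9, 0.0, fc)
    v00 = padded[r0, c0]
    v01 = padded[r0, c0 + 1]
    v10 = padded[r0 + 1, c0]
    v11 = padded[r0 + 1, c0 + 1]
    top = v00 * (1.0 - fc) + v01 * fc
    bot = v10 * (1.0 - fc) + v11 * fc
    return top * (1.0 - fr) + bot * fr


def _min_rotation_codes(codes: np.ndarray) -> np.ndarray:
    """Map each bit vector to the minimal cyclic rotation of its bit string.

    Bit 0 is the most significant position of the packed representation.
    """
    n, bits = codes.shape
    weights = 2 ** np.arange(bits - 1, -1, -1)
    best_val = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    best_rot = np.zeros(n, dtype=np.intp)
    for r in range(bits):
        rolled = np.roll(codes, -r, axis=1)
        vals = rolled.astype(np.int64) @ weights
        take = vals < best_val
        best_val[take] = vals[take]
        best_rot[take] = r
    out = np.empty_like(codes)
    for r in range(bits):
        sel = best_rot == r
        if np.any(sel):
            out[sel] = np.roll(codes[sel], -r, axis=1)
    return out


def extract_lbp(
    image: np.ndarray,
    pixels,
    scales: ScaleGrid,
    bits: int = 8,
    rotation_invariant: bool = False,
    slice_id: int = 0,
) -> MultiScaleFeatureSet:
    """Extract ``bits``-length LBP codes at every scale of the grid.

    Parameters
    ----------
    image : 2-D array (or RGB, converted to luminance grayscale).
    pixels : (n, 2) array of (row, col), or None for all pixels.
    scales : ScaleGrid of odd window sizes; radius = (size - 1) / 2.
    bits : number of ring neighbors (>= 4); default 8.
    rotation_invariant : map codes to their minimal cyclic rotation.
    """
    if bits < 4:
        raise ValueError("bits must be >= 4")
    img = as_gray_float(image)
    check_scales_fit(img.shape, scales)
    px = check_pixels(img.shape, pixels)
    pad = (max(scales.sizes) - 1) // 2 + 1
    padded = pad_reflect(img, pad)
    rows = px[:, 0] + pad
    cols = px[:, 1] + pad
    center = padded[rows, cols]

    angles = 2.0 * np.pi * np.arange(bits) / bits
    out = np.empty((len(px), len(scales), bits), dtype=np.float64)
    for si, size in enumerate(scales.sizes):
        radius = (size - 1) / 2.0
        dr = -radius * np.sin(angles)
        dc = radius * np.cos(angles)
        for b in range(bits):
            nb = _bilinear(padded, rows + dr[b], cols + dc[b])
            out[:, si, b] = (nb - center) >= -_TOL * (1.0 + np.abs(center))
        if rotation_invariant:
            out[:, si, :] = _min_rotation_codes(out[:, si, :].astype(np.uint8))
    return MultiScaleFeatureSet(
        family=Family.LBP,
        scales=scales,
        descriptors=out,
        pixel_coords=px,
        slice_ids=np.full(len(px), slice_id, dtype=np.intp),
    )
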