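"""Dense SIFT (PHOW-style) 128-length descriptors at multiple scales.

Each window size ``k`` maps to a SIFT spatial bin size ``m = ceil(k / 4)``;
the descriptor of a pixel is a 4 x 4 grid of spatial bins (flat box spatial
weighting), each holding an 8-bin gradient-orientation histogram with linear
(soft) assignment between adjacent orientation bins: 4 * 4 * 8 = 128 values,
L2-normalized.  Flat patches (gradient energy below 1e-10) yield the all-zero
descriptor.

The extraction is fully vectorized: eight orientation-channel maps are
box-filtered once per scale and then sampled at the sixteen bin centers of
every requested pixel.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter

from ..types import Family, MultiScaleFeatureSet, ScaleGrid
from ._util import as_gray_float, check_pixels, check_scales_fit, pad_reflect

N_ORIENTATIONS = 8
N_SPATIAL = 4  # 4 x 4 spatial bins
DESCRIPTOR_LENGTH = N_SPATIAL * N_SPATIAL * N_ORIENTATIONS
_FLAT_TOL = 1e-10


def bin_size_for_scale(size: int) -> int:
    return int(np.ceil(size / 4))


def _orientation_channels(img: np.ndarray) -> np.ndarray:
    """(8, H, W) soft-assigned gradient magnitude per orientation bin."""
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), 2.0 * np.pi)
    pos = ang / (2.0 * np.pi) * N_ORIENTATIONS  # in [0, 8)
    lo = np.floor(pos).astype(np.intp) % N_ORIENTATIONS
    hi = (lo + 1) % N_ORIENTATIONS
    w_hi = pos - np.floor(pos)
    channels = np.zeros((N_ORIENTATIONS, *img.shape))
    for o in range(N_ORIENTATIONS):
        channels[o] += np.where(lo == o, mag * (1.0 - w_hi), 0.0)
        channels[o] += np.where(hi == o, mag * w_hi, 0.0)
    return channels


def extract_phow(
    image: np.ndarray,
    pixels,
    scales: ScaleGrid,
    slice_id: int = 0,
) -> MultiScaleFeatureSet:
    """128-length dense-SIFT descriptor per pixel per scale."""
    img = as_gray_float(image)
    check_scales_fit(img.shape, scales)
    px = check_pixels(img.shape, pixels)

    # bin centers sit at offsets (b - 1.5) * m from the pixel, b = 0..3
    max_m = bin_size_for_scale(max(scales.sizes))
    pad = int(np.ceil(1.5 * max_m)) + max_m  # bin center + half a bin + slack
    padded = pad_reflect(img, pad)
    channels = _orientation_channels(padded)

    out = np.empty((len(px), len(scales), DESCRIPTOR_LENGTH))
    for si, size in enumerate(scales.sizes):
        m = bin_size_for_scale(size)
        # mean over each m x m spatial bin, per orientation channel
        binned = np.stack([uniform_filter(c, size=m, mode="nearest") for c in channels])
        offsets = np.round((np.arange(N_SPATIAL) - 1.5) * m).astype(np.intp)
        desc = np.empty((len(px), N_SPATIAL, N_SPATIAL, N_ORIENTATIONS))
        rows = px[:, 0] + pad
        cols = px[:, 1] + pad
        for bi, dr in enumerate(offsets):
            for bj, dc in enumerate(offsets):
                desc[:, bi, bj, :] = binned[:, rows + dr, cols + dc].T
        desc = desc.reshape(len(px), DESCRIPTOR_LENGTH)
        norms = np.linalg.norm(desc, axis=1)
        keep = norms > _FLAT_TOL
        desc[keep] /= norms[keep, None]
        desc[~keep] = 0.0
        out[:, si, :] = desc
    return MultiScaleFeatureSet(
        family=Family.PHOW,
        scales=scales,
        descriptors=out,
        pixel_coords=px,
        slice_ids=np.full(len(px), slice_id, dtype=np.intp),
    )
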