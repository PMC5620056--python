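"""Multi-scale Gabor filter-bank responses.

Each scale of side ``k`` maps to one complex Gabor kernel per orientation:
support ``k x k``, carrier wavelength ``lambda = k`` and Gaussian envelope
standard deviation ``sigma_g = 0.5 * lambda``, so the envelope (the "scale
factor" controlling the effective neighborhood) grows with the window.
Kernels are DC-corrected to exactly zero mean, making the response of a
constant image zero.  The descriptor entry for (pixel, scale, angle) is the
magnitude of the complex correlation response at that pixel.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from ..types import Family, MultiScaleFeatureSet, ScaleGrid
from ._util import as_gray_float, check_pixels, check_scales_fit, pad_reflect

DEFAULT_ANGLES = (0.0, 90.0, 180.0)


def gabor_kernel(size: int, angle_deg: float) -> np.ndarray:
    """Complex zero-mean Gabor kernel of support ``size x size``."""
    if size < 3 or size % 2 == 0:
        raise ValueError("kernel size must be odd and >= 3")
    r = (size - 1) // 2
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(np.float64)
    lam = float(size)
    sigma = 0.5 * lam
    theta = np.deg2rad(angle_deg)
    u = x * np.cos(theta) + y * np.sin(theta)
    envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    kern = envelope * np.exp(2j * np.pi * u / lam)
    return kern - kern.mean()


def extract_gabor(
    image: np.ndarray,
    pixels,
    scales: ScaleGrid,
    angles=DEFAULT_ANGLES,
    slice_id: int = 0,
) -> MultiScaleFeatureSet:
    """Gabor response magnitudes; descriptor length equals ``len(angles)``.

    The response at pixel p is the correlation sum
    ``sum_{u,v} image[p + (u, v)] * kernel[u, v]`` over the kernel support
    (reflect padding at borders), evaluated for every (scale, angle).
    """
    angles = tuple(float(a) for a in angles)
    if len(angles) == 0:
        raise ValueError("angle list must be non-empty")
    img = as_gray_float(image)
    check_scales_fit(img.shape, scales)
    px = check_pixels(img.shape, pixels)
    pad = scales.max_radius
    padded = pad_reflect(img, pad)

    out = np.empty((len(px), len(scales), len(angles)), dtype=np.float64)
    for si, size in enumerate(scales.sizes):
        for ai, ang in enumerate(angles):
            kern = gabor_kernel(size, ang)
            # correlation = convolution with the flipped kernel
            resp = fftconvolve(padded, kern[::-1, ::-1], mode="same")
            resp = resp[pad : pad + img.shape[0], pad : pad + img.shape[1]]
            out[:, si, ai] = np.abs(resp[px[:, 0], px[:, 1]])
    return MultiScaleFeatureSet(
        family=Family.GABOR,
        scales=scales,
        descriptors=out,
        pixel_coords=px,
        slice_ids=np.full(len(px), slice_id, dtype=np.intp),
    )
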