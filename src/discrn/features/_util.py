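"""Shared helpers for the per-family texture extractors."""

from __future__ import annotations

import numpy as np


def as_gray_float(image: np.ndarray) -> np.ndarray:
    """Coerce an input image to a 2-D float64 grayscale array.

    RGB(A) input is converted by luminance (0.299 R + 0.587 G + 0.114 B);
    integer images keep their native intensity range (no rescaling), since all
    extractors are either shift-invariant or quantize per window.
    """
    img = np.asarray(image)
    if img.ndim == 3 and img.shape[2] in (3, 4):
        rgb = img[..., :3].astype(np.float64)
        img = rgb @ np.array([0.299, 0.587, 0.114])
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    return img.astype(np.float64)


def check_pixels(shape: tuple[int, int], pixels) -> np.ndarray:
    """Validate (or generate) 0-based row-major pixel coordinates.

    ``pixels=None`` selects every pixel of the image.
    """
    h, w = shape
    if pixels is None:
        rr, cc = np.mgrid[0:h, 0:w]
        return np.column_stack([rr.ravel(), cc.ravel()])
    px = np.atleast_2d(np.asarray(pixels, dtype=np.intp))
    if px.ndim != 2 or px.shape[1] != 2:
        raise ValueError("pixels must be an (n, 2) array of (row, col)")
    if px.size and (
        px[:, 0].min() < 0 or px[:, 1].min() < 0
        or px[:, 0].max() >= h or px[:, 1].max() >= w
    ):
        raise ValueError("pixel coordinates fall outside the image")
    return px


def check_scales_fit(shape: tuple[int, int], sizes) -> None:
    side = min(shape)
    for s in sizes:
        if s > side:
            raise ValueError(
                f"scale {s} exceeds the smallest image side ({side})"
            )


def pad_reflect(img: np.ndarray, radius: int) -> np.ndarray:
    """Reflect-pad by ``radius`` so windows centred on border pixels exist."""
    return np.pad(img, radius, mode="reflect")
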