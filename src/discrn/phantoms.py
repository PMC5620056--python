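"""Seeded two-class textured phantoms with a planted discriminative scale.

The generator emulates the geometry of a lesion-detection study: a textured
background, an elliptical lesion whose texture differs from the background
only in a controlled way, and a binary ground-truth mask.  The background is
an oriented sinusoidal grating whose spatial period equals the planted
window scale, buried in i.i.d. Gaussian pixel noise; inside the lesion the
grating amplitude is multiplied by ``1 + effect_size``, so the class
difference is an amplitude contrast concentrated at the planted spatial
frequency.  ``effect_size = 0`` makes lesion and background statistically
identical (the null phantom), and larger effects are monotonically easier.

The grating is deliberately *weak* relative to the pixel noise
(amplitude 12 vs. noise std 10 on a 0-255 scale): a high-contrast coherent
grating would dominate the superpixel segmentation (stripe-shaped regions,
biasing center-based negative sampling toward grating extrema) and leave a
conspicuous phase defect in the reflect-padded border band, both of which
couple pixel scores to lesion geometry even when ``effect_size = 0``.

A direct kernel fixture is also provided to exercise the scale-weight
optimizer without going through image space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .learning import DistanceKernels, assemble_kernels

BASE_INTENSITY = 128.0
GRATING_AMPLITUDE = 12.0
GRATING_ANGLE_DEG = 0.0  # stripes vary along columns


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    ``effect_size`` is the relative amplitude contrast of the lesion grating
    (0 = null); ``noise_sd`` the std of additive Gaussian noise in intensity
    units on a 0-255 scale.
    """

    height: int = 128
    width: int = 128
    lesion_center: tuple[float, float] = (64.0, 64.0)  # (row, col)
    lesion_axes: tuple[float, float] = (18.0, 12.0)  # semi-axes (row, col)
    planted_scale: int = 7
    effect_size: float = 1.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        cy, cx = self.lesion_center
        ay, ax = self.lesion_axes
        if ay <= 0 or ax <= 0:
            raise ValueError("lesion axes must be positive")
        if (cy - ay < 0 or cy + ay >= self.height
                or cx - ax < 0 or cx + ax >= self.width):
            raise ValueError("lesion ellipse must lie fully inside the image")
        if self.planted_scale < 3 or self.planted_scale % 2 == 0:
            raise ValueError("planted_scale must be odd and >= 3")


def ellipse_mask(spec: PhantomSpec) -> np.ndarray:
    cy, cx = spec.lesion_center
    ay, ax = spec.lesion_axes
    rr, cc = np.mgrid[0 : spec.height, 0 : spec.width]
    return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (image, mask): float image in [0, 255] and boolean lesion mask."""
    rng = np.random.default_rng(spec.seed)
    rr, cc = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
    theta = np.deg2rad(GRATING_ANGLE_DEG)
    u = cc * np.cos(theta) + rr * np.sin(theta)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    grating = np.sin(2.0 * np.pi * u / spec.planted_scale + phase)

    mask = ellipse_mask(spec)
    amplitude = np.where(mask, GRATING_AMPLITUDE * (1.0 + spec.effect_size),
                         GRATING_AMPLITUDE)
    image = BASE_INTENSITY + amplitude * grating
    image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    return np.clip(image, 0.0, 255.0), mask


def generate_study(
    n_slices: int,
    seed: int = 0,
    height: int = 128,
    width: int = 128,
    planted_scale: int = 7,
    effect_size: float = 1.0,
    noise_sd: float = 10.0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """A set of slices with randomized lesion geometry (seeded).

    Lesion centers and semi-axes vary from slice to slice, as lesions do
    across patients; texture parameters are held at the study condition.
    """
    rng = np.random.default_rng(seed)
    images, masks = [], []
    for _ in range(n_slices):
        ay = rng.uniform(0.10, 0.16) * height
        ax = rng.uniform(0.08, 0.13) * width
        cy = rng.uniform(ay + 2, height - ay - 3)
        cx = rng.uniform(ax + 2, width - ax - 3)
        spec = PhantomSpec(
            height=height, width=width,
            lesion_center=(cy, cx), lesion_axes=(ay, ax),
            planted_scale=planted_scale, effect_size=effect_size,
            noise_sd=noise_sd, seed=int(rng.integers(0, 2**31 - 1)),
        )
        img, mask = generate_phantom(spec)
        images.append(img)
        masks.append(mask)
    return images, masks


def generate_kernel_fixture(
    S: int,
    s_star: int,
    gap: float,
    n_pairs: int,
    seed: int = 0,
) -> DistanceKernels:
    """Distance kernels with planted between-class signal at scale ``s_star``.

    Within-class distance columns are homogeneous across scales
    (|N(1, 0.1)| entries); between-class columns draw scale ``s_star``
    (0-based) with mean ``gap`` times the others.  ``gap = 1`` makes all
    scales exchangeable.
    """
    if not 0 <= s_star < S:
        raise ValueError("s_star must be a valid 0-based scale index")
    if gap < 1:
        raise ValueError("gap must be >= 1")
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    rng = np.random.default_rng(seed)
    H_p = np.abs(rng.normal(1.0, 0.1, size=(S, n_pairs)))
    means = np.ones(S)
    means[s_star] = gap
    H_b = np.abs(rng.normal(means[:, None], 0.1 * means[:, None],
                            size=(S, n_pairs)))
    return assemble_kernels(H_p, H_b)
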