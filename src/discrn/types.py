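"""Shared domain types: feature families, scale grids, descriptor containers.

A *scale* is the side length of the square (or diameter of the circular)
neighborhood a texture descriptor summarizes.  Four texture families are
supported; each produces a fixed-length descriptor per pixel per scale:

======== ==================== =================
family   descriptor length    distance metric
======== ==================== =================
LBP      ``bits`` (default 8) Hamming
GABOR    number of angles     Euclidean
HARALICK 14                   Euclidean
PHOW     128                  Euclidean
======== ==================== =================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Family(str, Enum):
    """Texture feature family."""

    LBP = "lbp"
    GABOR = "gabor"
    HARALICK = "haralick"
    PHOW = "phow"


class Metric(str, Enum):
    HAMMING = "hamming"
    EUCLIDEAN = "euclidean"


#: canonical per-family distance metric
METRIC_FOR_FAMILY: dict[Family, Metric] = {
    Family.LBP: Metric.HAMMING,
    Family.GABOR: Metric.EUCLIDEAN,
    Family.HARALICK: Metric.EUCLIDEAN,
    Family.PHOW: Metric.EUCLIDEAN,
}


@dataclass(frozen=True)
class DistanceMetricSpec:
    """Pairing of a feature family with its per-scale base distance."""

    family: Family
    metric: Metric

    def __post_init__(self) -> None:
        expected = METRIC_FOR_FAMILY[Family(self.family)]
        if Metric(self.metric) != expected:
            raise ValueError(
                f"{Family(self.family).value} uses the {expected.value} distance"
            )

    @classmethod
    def for_family(cls, family: Family) -> "DistanceMetricSpec":
        return cls(family=Family(family), metric=METRIC_FOR_FAMILY[Family(family)])


@dataclass(frozen=True)
class ScaleGrid:
    """Ordered grid of odd square window side-lengths, e.g. (3, 5, 7).

    Raises ``ValueError`` unless sizes are odd, strictly increasing and >= 3.
    """

    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        object.__setattr__(self, "sizes", sizes)
        if len(sizes) < 1:
            raise ValueError("scale grid must contain at least one size")
        for s in sizes:
            if s < 3 or s % 2 == 0:
                raise ValueError(f"scale sizes must be odd and >= 3, got {s}")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("scale sizes must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sizes)

    def __iter__(self):
        return iter(self.sizes)

    def index(self, size: int) -> int:
        return self.sizes.index(size)

    @property
    def max_radius(self) -> int:
        return (max(self.sizes) - 1) // 2


@dataclass
class MultiScaleFeatureSet:
    """Per-pixel descriptors for one feature family across a scale grid.

    ``descriptors`` has shape ``(n_pixels, S, d)`` where ``S = len(scales)``
    and ``d`` is the family's fixed descriptor length.  ``pixel_coords`` is an
    ``(n_pixels, 2)`` array of 0-based (row, col) positions, row-major.
    ``slice_ids`` tags each sample with the image/slice it came from so that
    pairwise distances can be grouped per slice.
    """

    family: Family
    scales: ScaleGrid
    descriptors: np.ndarray
    pixel_coords: np.ndarray
    slice_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.descriptors = np.asarray(self.descriptors, dtype=np.float64)
        self.pixel_coords = np.asarray(self.pixel_coords, dtype=np.intp)
        if self.descriptors.ndim != 3:
            raise ValueError("descriptors must have shape (n_pixels, S, d)")
        n, S, _ = self.descriptors.shape
        if S != len(self.scales):
            raise ValueError("descriptor scale axis does not match scale grid")
        if self.pixel_coords.shape != (n, 2):
            raise ValueError("pixel_coords must have shape (n_pixels, 2)")
        if self.slice_ids is None:
            self.slice_ids = np.zeros(n, dtype=np.intp)
        else:
            self.slice_ids = np.asarray(self.slice_ids, dtype=np.intp)
            if self.slice_ids.shape != (n,):
                raise ValueError("slice_ids must have shape (n_pixels,)")

    @property
    def n_pixels(self) -> int:
        return self.descriptors.shape[0]

    @property
    def descriptor_length(self) -> int:
        return self.descriptors.shape[2]
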