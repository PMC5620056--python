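"""Family dispatch and fixed-order feature-matrix assembly.

Training and exhaustive test-time labeling must lay descriptors out in the
same column order; ``assemble_features`` guarantees it: families in the fixed
order LBP, GABOR, HARALICK, PHOW, scales ascending within each family,
descriptor entries contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ..types import Family, MultiScaleFeatureSet, ScaleGrid
from .gabor import DEFAULT_ANGLES, extract_gabor
from .haralick import extract_haralick
from .lbp import extract_lbp
from .phow import extract_phow

FAMILY_ORDER = (Family.LBP, Family.GABOR, Family.HARALICK, Family.PHOW)


@dataclass(frozen=True)
class FeatureParams:
    """Fixed per-family extraction parameters."""

    lbp_bits: int = 8
    lbp_rotation_invariant: bool = False
    gabor_angles: tuple[float, ...] = DEFAULT_ANGLES
    gray_levels: int = 32


def extract_family(
    image: np.ndarray,
    pixels,
    family: Family,
    scales: ScaleGrid,
    params: FeatureParams = FeatureParams(),
    slice_id: int = 0,
) -> MultiScaleFeatureSet:
    family = Family(family)
    if family == Family.LBP:
        return extract_lbp(
            image, pixels, scales, bits=params.lbp_bits,
            rotation_invariant=params.lbp_rotation_invariant, slice_id=slice_id,
        )
    if family == Family.GABOR:
        return extract_gabor(
            image, pixels, scales, angles=params.gabor_angles, slice_id=slice_id
        )
    if family == Family.HARALICK:
        return extract_haralick(
            image, pixels, scales, gray_levels=params.gray_levels, slice_id=slice_id
        )
    return extract_phow(image, pixels, scales, slice_id=slice_id)


def assemble_features(
    image: np.ndarray,
    pixels,
    selections: Mapping[Family, Sequence[int]],
    params: FeatureParams = FeatureParams(),
) -> tuple[np.ndarray, int]:
    """Stack descriptors at the selected scales of each family.

    ``selections`` maps family -> window sizes to extract (empty sequences
    are skipped).  Returns the (n_pixels, D) matrix and the number of
    (family, scale) descriptor sets extracted.
    """
    blocks: list[np.ndarray] = []
    n_pairs = 0
    for family in FAMILY_ORDER:
        sizes = sorted(selections.get(family, ()))
        if not sizes:
            continue
        grid = ScaleGrid(tuple(sizes))
        fs = extract_family(image, pixels, family, grid, params=params)
        n, S, d = fs.descriptors.shape
        blocks.append(fs.descriptors.reshape(n, S * d))
        n_pairs += S
    if not blocks:
        raise ValueError("no (family, scale) selections to extract")
    return np.hstack(blocks), n_pairs
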