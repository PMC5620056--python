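"""Per-scale base distances between multi-scale descriptors.

The weighted multi-scale dissimilarity is ``w . h`` where ``h`` stacks the
per-scale base distances ``h(x_s, x'_s)``: Hamming for LBP bit codes,
Euclidean for the other three families.
"""

from __future__ import annotations

import numpy as np

from ..types import DistanceMetricSpec, Metric, MultiScaleFeatureSet


def pairwise_scale_distances(
    A: MultiScaleFeatureSet,
    B: MultiScaleFeatureSet,
    metric: DistanceMetricSpec | None = None,
    pairs: np.ndarray | None = None,
) -> np.ndarray:
    """Distance vectors ``h`` of length S for descriptor pairs from A and B.

    Parameters
    ----------
    pairs : (n_pairs, 2) index array (i into A, j into B); ``None``
        enumerates the full Cartesian product of A's and B's samples.

    Returns
    -------
    (S, n_pairs) array; column p is the per-scale distance vector of pair p.
    """
    if A.family != B.family:
        raise ValueError(f"feature family mismatch: {A.family} vs {B.family}")
    if A.scales != B.scales:
        raise ValueError("scale grids differ between the two feature sets")
    if metric is None:
        metric = DistanceMetricSpec.for_family(A.family)
    elif metric.family != A.family:
        raise ValueError("metric spec family does not match the feature sets")

    if pairs is None:
        ii, jj = np.meshgrid(
            np.arange(A.n_pixels), np.arange(B.n_pixels), indexing="ij"
        )
        pairs = np.column_stack([ii.ravel(), jj.ravel()])
    else:
        pairs = np.asarray(pairs, dtype=np.intp)

    da = A.descriptors[pairs[:, 0]]  # (n_pairs, S, d)
    db = B.descriptors[pairs[:, 1]]
    diff = da - db
    if metric.metric == Metric.HAMMING:
        h = np.abs(diff).sum(axis=2)
    else:
        h = np.sqrt(np.einsum("psd,psd->ps", diff, diff))
    return h.T  # (S, n_pairs)
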