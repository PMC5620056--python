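"""End-to-end lesion detection: superpixels, balanced sampling, Random
Forest classification at the selected scales, and heatmap smoothing.

Training: (1) SLIC superpixels on each slice; (2) balanced sampling — every
lesion pixel, plus one center per fully-negative superpixel, topped up or
subsampled to match counts; (3) per-family discriminative scale learning on
sampled descriptors; (4) a Random Forest on the selected-scale descriptor
matrix.  Testing: exhaustive per-pixel labeling at the selected scales gives
a probability heatmap, which is quantized to the eleven levels
{0, 0.1, ..., 1} and smoothed by per-superpixel majority vote.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage.segmentation import slic as _skimage_slic
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .features import FAMILY_ORDER, FeatureParams, assemble_features, extract_family
from .features._util import as_gray_float
from .learning import ScaleWeights, build_distance_kernels, learn_scale_weights
from .types import Family, MultiScaleFeatureSet, ScaleGrid

logger = logging.getLogger(__name__)

LEVELS = np.round(np.arange(11) / 10.0, 1)  # {0, 0.1, ..., 1}


@dataclass
class SuperpixelMap:
    """Integer label image partitioning pixels into homogeneous regions."""

    labels: np.ndarray
    rSize: int
    reqStr: float

    @property
    def n_regions(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class TrainingSampleSet:
    positive_coords: np.ndarray  # (n, 2)
    negative_coords: np.ndarray  # (n, 2)
    slice_id: int = 0


@dataclass
class ProbabilityHeatmap:
    probs: np.ndarray
    quantized: bool = False


def segment_superpixels(image: np.ndarray, rSize: int = 8,
                        reqStr: float = 0.01) -> SuperpixelMap:
    """SLIC superpixels with nominal size ``rSize`` and regularization ``reqStr``.

    The image is normalized to [0, 1] and ``reqStr`` is mapped to the
    skimage SLIC compactness as ``100 * reqStr`` (regularizer scales are
    implementation-specific; this calibration makes the reference default
    reqStr = 0.01 produce balanced, compact regions on that fixed intensity
    range).  Images smaller than ``rSize`` in either dimension collapse to a
    single region.
    """
    if rSize < 2:
        raise ValueError("rSize must be >= 2")
    img = as_gray_float(image)
    h, w = img.shape
    if min(h, w) < rSize:
        return SuperpixelMap(np.zeros((h, w), dtype=np.intp), rSize, reqStr)
    rng_span = img.max() - img.min()
    norm = (img - img.min()) / rng_span if rng_span > 0 else np.zeros_like(img)
    n_segments = max(1, round(h * w / rSize**2))
    labels = _skimage_slic(
        norm, n_segments=n_segments, compactness=100.0 * reqStr,
        start_label=0, channel_axis=None, enforce_connectivity=True,
    )
    # compact the label range (SLIC can skip labels after merging)
    _, labels = np.unique(labels, return_inverse=True)
    return SuperpixelMap(labels.reshape(h, w).astype(np.intp), rSize, reqStr)


def _region_centers(spx: SuperpixelMap, region_ids: np.ndarray) -> np.ndarray:
    """One representative pixel per region: the member closest to the centroid."""
    lab = spx.labels
    rows, cols = np.indices(lab.shape)
    centers = np.empty((len(region_ids), 2), dtype=np.intp)
    for k, rid in enumerate(region_ids):
        mask = lab == rid
        rr, cc = rows[mask], cols[mask]
        cy, cx = rr.mean(), cc.mean()
        j = np.argmin((rr - cy) ** 2 + (cc - cx) ** 2)
        centers[k] = rr[j], cc[j]
    return centers


def sample_balanced_training(mask: np.ndarray, spx: SuperpixelMap,
                             seed: int = 0) -> TrainingSampleSet:
    """Balanced positive/negative pixel sampling driven by superpixels.

    All lesion pixels are positives.  Negatives start from one center pixel
    per fully-negative superpixel; if those exceed the positive count a
    seeded subsample of centers is used, otherwise additional negative
    pixels are drawn uniformly (seeded) until the classes balance.
    """
    mask = np.asarray(mask) > 0
    if mask.shape != spx.labels.shape:
        raise ValueError("mask and superpixel map shapes differ")
    n_pos_px = int(mask.sum())
    if n_pos_px == 0 or n_pos_px == mask.size:
        raise ValueError("mask must contain both lesion and background pixels")
    rng = np.random.default_rng(seed)

    pos = np.argwhere(mask)
    lab = spx.labels
    pos_regions = np.unique(lab[mask])
    all_regions = np.arange(spx.n_regions)
    neg_regions = np.setdiff1d(all_regions, pos_regions)
    centers = _region_centers(spx, neg_regions) if len(neg_regions) else np.empty((0, 2), dtype=np.intp)

    n_pos = len(pos)
    if len(centers) >= n_pos:
        take = rng.choice(len(centers), size=n_pos, replace=False)
        neg = centers[np.sort(take)]
    else:
        chosen = {(int(r), int(c)) for r, c in centers}
        pool = np.argwhere(~mask)
        pool_keys = [(int(r), int(c)) for r, c in pool]
        avail = np.array([k not in chosen for k in pool_keys])
        pool = pool[avail]
        need = n_pos - len(centers)
        if need > len(pool):
            raise ValueError("not enough negative pixels to balance the classes")
        extra = pool[np.sort(rng.choice(len(pool), size=need, replace=False))]
        neg = np.vstack([centers, extra]) if len(centers) else extra
    return TrainingSampleSet(positive_coords=pos, negative_coords=neg)


def train_classifier(features: np.ndarray, labels: np.ndarray,
                     n_trees: int = 50, seed: int = 0) -> RandomForestClassifier:
    """Random Forest on the (samples x descriptors) matrix."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    clf.fit(np.asarray(features, dtype=np.float64), labels)
    return clf


def classify_image(
    clf: RandomForestClassifier,
    image: np.ndarray,
    selections: Mapping[Family, Sequence[int]],
    params: FeatureParams = FeatureParams(),
) -> ProbabilityHeatmap:
    """Exhaustive per-pixel labeling at the selected scales of each family."""
    if not any(len(v) for v in selections.values()):
        raise ValueError("every family has an empty scale selection")
    img = as_gray_float(image)
    X, n_pairs = assemble_features(img, None, selections, params=params)
    probs = clf.predict_proba(X)[:, 1].reshape(img.shape)
    logger.info("classified %s pixels using %d (family, scale) descriptor sets",
                img.shape, n_pairs)
    return ProbabilityHeatmap(probs=probs, quantized=False)


def quantize_probs(probs: np.ndarray) -> np.ndarray:
    """Round half-up to the nearest level in {0, 0.1, ..., 1}."""
    idx = np.floor(np.asarray(probs, dtype=np.float64) * 10.0 + 0.5).astype(np.intp)
    return LEVELS[np.clip(idx, 0, 10)]


def smooth_heatmap(hm: ProbabilityHeatmap, spx: SuperpixelMap) -> ProbabilityHeatmap:
    """Quantize then majority-vote each superpixel to a single level.

    Ties between equally frequent levels break toward the smaller level.
    """
    if hm.probs.shape != spx.labels.shape:
        raise ValueError("heatmap and superpixel map shapes differ")
    q = quantize_probs(hm.probs)
    level_idx = np.rint(q * 10.0).astype(np.intp)
    lab = spx.labels.ravel()
    counts = np.bincount(lab * 11 + level_idx.ravel(),
                         minlength=spx.n_regions * 11).reshape(-1, 11)
    modal = counts.argmax(axis=1)  # first max -> smallest level on ties
    out = LEVELS[modal][spx.labels]
    return ProbabilityHeatmap(probs=out, quantized=True)


def evaluate_auc(hm: ProbabilityHeatmap | np.ndarray, mask: np.ndarray,
                 roi: np.ndarray | None = None) -> float:
    """Rank-based (midrank-tie) AUC of the heatmap against the lesion mask.

    ``roi`` optionally restricts evaluation to a region of interest.
    """
    probs = hm.probs if isinstance(hm, ProbabilityHeatmap) else np.asarray(hm)
    y = (np.asarray(mask) > 0).ravel()
    s = probs.ravel()
    if roi is not None:
        sel = np.asarray(roi).ravel() > 0
        y, s = y[sel], s[sel]
    if y.all() or not y.any():
        raise ValueError("mask must contain both classes within the evaluated domain")
    return float(roc_auc_score(y, s))


# ---------------------------------------------------------------------------
# high-level train / predict
# ---------------------------------------------------------------------------

@dataclass
class DetectorConfig:
    """Pipeline parameters; defaults follow the method's reference setting."""

    scales: tuple[int, ...] = (3, 5, 7)
    alpha: float = 0.1
    eta: float = 0.001
    sigma: float = 0.3
    rSize: int = 8
    reqStr: float = 0.01
    n_trees: int = 50
    pairs_per_slice: int = 2000
    features: FeatureParams = field(default_factory=FeatureParams)


@dataclass
class DiscrnDetector:
    """Trained model: per-family scale weights/selections plus the forest."""

    config: DetectorConfig
    weights: dict[Family, ScaleWeights]
    selections: dict[Family, tuple[int, ...]]
    classifier: RandomForestClassifier

    @property
    def n_descriptor_sets(self) -> int:
        return sum(len(v) for v in self.selections.values())


def learn_family_weights(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    samples: Sequence[TrainingSampleSet],
    config: DetectorConfig,
    seed: int = 0,
) -> dict[Family, ScaleWeights]:
    """Independently learn scale weights for each of the four families."""
    grid = ScaleGrid(config.scales)
    out: dict[Family, ScaleWeights] = {}
    for fi, family in enumerate(FAMILY_ORDER):
        pos_sets, neg_sets = [], []
        for t, (img, smp) in enumerate(zip(images, samples)):
            pos_sets.append(extract_family(img, smp.positive_coords, family, grid,
                                           params=config.features, slice_id=t))
            neg_sets.append(extract_family(img, smp.negative_coords, family, grid,
                                           params=config.features, slice_id=t))
        pos = _concat_feature_sets(pos_sets)
        neg = _concat_feature_sets(neg_sets)
        kernels = build_distance_kernels(
            pos, neg, pairs_per_slice=config.pairs_per_slice,
            seed=seed * 7919 + fi,
        )
        out[family] = learn_scale_weights(
            kernels, alpha=config.alpha, eta=config.eta, sigma=config.sigma,
            scale_sizes=grid.sizes,
        )
        logger.info("%s: w=%s selected sizes=%s", family.value,
                    np.round(out[family].w, 3), out[family].selected_sizes)
    return out


def _concat_feature_sets(sets: Sequence[MultiScaleFeatureSet]) -> MultiScaleFeatureSet:
    return MultiScaleFeatureSet(
        family=sets[0].family,
        scales=sets[0].scales,
        descriptors=np.concatenate([s.descriptors for s in sets]),
        pixel_coords=np.concatenate([s.pixel_coords for s in sets]),
        slice_ids=np.concatenate([s.slice_ids for s in sets]),
    )


def fit_detector(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    config: DetectorConfig = DetectorConfig(),
    seed: int = 0,
    use_all_scales: bool = False,
) -> DiscrnDetector:
    """Train the full pipeline on labeled slices.

    ``use_all_scales=True`` skips discriminative scale selection and trains
    on every (family, scale) pair — the comparison baseline.
    """
    if len(images) != len(masks) or not images:
        raise ValueError("need equally many images and masks, at least one each")
    samples = [
        sample_balanced_training(mask, segment_superpixels(img, config.rSize, config.reqStr),
                                 seed=seed * 31 + t)
        for t, (img, mask) in enumerate(zip(images, masks))
    ]
    if use_all_scales:
        weights = {}
        selections = {f: tuple(config.scales) for f in FAMILY_ORDER}
    else:
        weights = learn_family_weights(images, masks, samples, config, seed=seed)
        selections = {f: w.selected_sizes for f, w in weights.items()}
        total = len(FAMILY_ORDER) * len(config.scales)
        used = sum(len(s) for s in selections.values())
        logger.info("descriptor sets: %d of %d (%.0f%% of all-scales cost)",
                    used, total, 100.0 * used / total)

    X_blocks, y_blocks = [], []
    for img, smp in zip(images, samples):
        coords = np.vstack([smp.positive_coords, smp.negative_coords])
        X, _ = assemble_features(img, coords, selections, params=config.features)
        X_blocks.append(X)
        y_blocks.append(np.concatenate([
            np.ones(len(smp.positive_coords), dtype=np.intp),
            np.zeros(len(smp.negative_coords), dtype=np.intp),
        ]))
    clf = train_classifier(np.vstack(X_blocks), np.concatenate(y_blocks),
                           n_trees=config.n_trees, seed=seed)
    return DiscrnDetector(config=config, weights=weights,
                          selections=selections, classifier=clf)


def predict_heatmap(
    detector: DiscrnDetector,
    image: np.ndarray,
    smooth: bool = True,
) -> tuple[ProbabilityHeatmap, ProbabilityHeatmap | None]:
    """Raw and (optionally) superpixel-smoothed probability heatmaps.

    Test-time superpixels are recomputed on the test image with the training
    rSize/reqStr.
    """
    raw = classify_image(detector.classifier, image, detector.selections,
                         params=detector.config.features)
    if not smooth:
        return raw, None
    spx = segment_superpixels(image, detector.config.rSize, detector.config.reqStr)
    return raw, smooth_heatmap(raw, spx)
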