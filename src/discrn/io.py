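"""Reading/writing images, masks, heatmaps and pipeline configuration."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .features import FeatureParams
from .pipeline import DetectorConfig, ProbabilityHeatmap


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image (8- or 16-bit, gray or RGB) as float64."""
    return np.asarray(iio.imread(str(path))).astype(np.float64)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel binary mask; any value > 0 marks the lesion."""
    m = np.asarray(iio.imread(str(path)))
    if m.ndim == 3:
        m = m[..., 0]
    return m > 0


def write_image_u8(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(str(path), np.clip(image, 0, 255).astype(np.uint8))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(str(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def write_heatmap(path: str | Path, hm: ProbabilityHeatmap) -> None:
    """16-bit PNG (probability x 65535) plus a float CSV sidecar."""
    path = Path(path)
    scaled = np.clip(hm.probs, 0.0, 1.0) * 65535.0
    iio.imwrite(str(path), np.rint(scaled).astype(np.uint16))
    np.savetxt(path.with_suffix(".csv"), hm.probs, delimiter=",", fmt="%.6f")


def read_heatmap(path: str | Path) -> ProbabilityHeatmap:
    csv = Path(path).with_suffix(".csv")
    if csv.exists():
        probs = np.loadtxt(csv, delimiter=",")
    else:
        probs = np.asarray(iio.imread(str(path))).astype(np.float64) / 65535.0
    return ProbabilityHeatmap(probs=probs)


def write_feature_table(path: str | Path, fs) -> None:
    """Serialize a feature set to a columnar CSV cache:
    row, col, slice, family, scale, d0..d{k-1}."""
    n, S, d = fs.descriptors.shape
    header = "row,col,slice,family,scale," + ",".join(f"d{i}" for i in range(d))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i in range(n):
            r, c = fs.pixel_coords[i]
            for si, size in enumerate(fs.scales.sizes):
                vals = ",".join(repr(float(v)) for v in fs.descriptors[i, si])
                fh.write(f"{r},{c},{fs.slice_ids[i]},{fs.family.value},{size},{vals}\n")


def read_feature_table(path: str | Path):
    """Load a feature set written by :func:`write_feature_table`."""
    from .types import Family, MultiScaleFeatureSet, ScaleGrid

    rows = Path(path).read_text().strip().splitlines()
    body = [line.split(",") for line in rows[1:]]
    family = Family(body[0][3])
    sizes = tuple(sorted({int(b[4]) for b in body}))
    grid = ScaleGrid(sizes)
    keyed = {}
    for b in body:
        key = (int(b[0]), int(b[1]), int(b[2]))
        keyed.setdefault(key, {})[int(b[4])] = [float(v) for v in b[5:]]
    coords = sorted(keyed)
    desc = np.array([[keyed[k][s] for s in sizes] for k in coords])
    return MultiScaleFeatureSet(
        family=family, scales=grid, descriptors=desc,
        pixel_coords=np.array([(r, c) for r, c, _ in coords]),
        slice_ids=np.array([t for _, _, t in coords]),
    )


def load_config(path: str | Path) -> DetectorConfig:
    """Detector configuration from YAML/JSON; ``mu`` is accepted as an alias
    for the sparsity controller ``eta``."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    feat = raw.pop("features", {}) or {}
    if "mu" in raw and "eta" not in raw:
        raw["eta"] = raw.pop("mu")
    raw.pop("mu", None)
    if "gabor_angles" in feat:
        feat["gabor_angles"] = tuple(feat["gabor_angles"])
    if "scales" in raw:
        raw["scales"] = tuple(raw["scales"])
    return DetectorConfig(features=FeatureParams(**feat), **raw)


def save_config(path: str | Path, config: DetectorConfig) -> None:
    d = {
        "scales": list(config.scales),
        "alpha": config.alpha,
        "eta": config.eta,
        "sigma": config.sigma,
        "rSize": config.rSize,
        "reqStr": config.reqStr,
        "n_trees": config.n_trees,
        "pairs_per_slice": config.pairs_per_slice,
        "features": {
            "lbp_bits": config.features.lbp_bits,
            "lbp_rotation_invariant": config.features.lbp_rotation_invariant,
            "gabor_angles": list(config.features.gabor_angles),
            "gray_levels": config.features.gray_levels,
        },
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
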