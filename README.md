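# discrn

Discriminative scale learning for multi-scale texture features, with a
superpixel-aware lesion-detection pipeline.

## The problem

Pixel-level detection of lesions (e.g. prostate cancer on T2w/ADC MRI or
digitized biopsy slides) typically extracts texture descriptors — Local
Binary Patterns, a Gabor filter bank, Haralick co-occurrence statistics,
dense SIFT (PHOW) — at several neighborhood *scales* (window sizes) and
feeds them all to a classifier.  Most scales are redundant for any given
task, and extraction cost grows linearly with the number of (family, scale)
pairs — prohibitive on large histology images.  `discrn` learns which scales
actually discriminate and extracts only those, cutting extraction cost
substantially while preserving (often slightly improving) accuracy.

## The method

For each feature family, per-scale base distances `h(x_s, x'_s)` (Hamming
for LBP codes, Euclidean otherwise) are collected into the intra-class and
inter-class distance kernels `S_p = H_p H_pᵀ` and `S_b = H_b H_bᵀ`, from
within-positive and positive-versus-negative pixel pairs sampled per slice.
A sparse nonnegative scale-weight vector `w` maximizes the discriminant
ratio `wᵀS_b w / wᵀS_p w`, solved through an ℓ1-regularized least-squares
reformulation (with `R_pᵀR_p` the Cholesky factorization of `S_p`) by
alternating

* an exact sparse nonnegative least-squares w-step (block principal
  pivoting), and
* the closed-form a-step `a = R_p⁻ᵀ S_b w / sqrt(wᵀ S_b S_b w)`.

Scales with `w_s ≥ σ·max(w)` (default σ = 0.3) are kept.  A Random Forest
trained on balanced, superpixel-guided samples at the selected scales then
labels every pixel of a test image; the probability map is quantized to
{0, 0.1, …, 1} and smoothed by per-superpixel majority vote.  See
`docs/methods.md` for the full model, conventions, and defaults
(α = 0.1, η = 0.001, σ = 0.3, SLIC rSize = 8 / reqStr = 0.01, 50 trees).

Because no clinical images ship with the package, a seeded phantom
generator produces two-class textured images whose class difference is
planted at a known scale, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from discrn import generate_study, fit_detector, predict_heatmap, evaluate_auc

images, masks = generate_study(4, seed=7, height=64, width=64)
detector = fit_detector(images[:3], masks[:3], seed=0)
for family, w in detector.weights.items():
    print(f"{family.value:9s} w = {np.round(w.w, 3)}  selected scales: {w.selected_sizes}")
raw, smoothed = predict_heatmap(detector, images[3])
print(f"descriptor sets: {detector.n_descriptor_sets} of 12")
print(f"test AUC (raw)      = {evaluate_auc(raw, masks[3]):.3f}")
print(f"test AUC (smoothed) = {evaluate_auc(smoothed, masks[3]):.3f}")
```

prints

```
lbp       w = [0.863 0.    0.505]  selected scales: (3, 7)
gabor     w = [0. 0. 1.]  selected scales: (7,)
haralick  w = [0. 0. 1.]  selected scales: (7,)
phow      w = [0.    0.707 0.707]  selected scales: (5, 7)
descriptor sets: 6 of 12
test AUC (raw)      = 0.993
test AUC (smoothed) = 0.761
```

The phantoms plant their discriminative signal at the 7×7 scale: the
spectrally tuned families (Gabor, Haralick) put all their weight there, and
the detector extracts 6 of the 12 possible (family, scale) descriptor sets —
half the extraction cost — while ranking lesion pixels essentially perfectly
(raw AUC 0.993).  The smoothed AUC is lower on these small 64×64 images
because quantized majority voting coarsens scores to a handful of levels;
it trades ranking resolution for spatially coherent maps.

The same pipeline is available from the shell:

```bash
discrn simulate --spec spec.yaml --out slice0/        # image.png, mask.png, spec.json
discrn learn-scales --image a.png --mask a_mask.png --out weights/
discrn train --image a.png --mask a_mask.png --out model.joblib
discrn predict --model model.joblib --image b.png --out heatmap.png
discrn evaluate --heatmap heatmap.png --mask b_mask.png
```

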