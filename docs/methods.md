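# Methods

## Problem and model

Multi-scale texture descriptors — Local Binary Patterns (LBP), a Gabor
filter bank, Haralick co-occurrence statistics, and dense SIFT (PHOW) —
describe a pixel's neighborhood at several window sizes (*scales*).
Extracting every family at every scale is expensive, and for a given
discrimination task most scales are redundant.  `discrn` learns, per feature
family, a sparse nonnegative weight vector `w ∈ R^S` over the S scales such
that the weighted dissimilarity `H(x, x') = Σ_s w_s h(x_s, x'_s)` separates
a positive (lesion) pixel class from a negative (background) class; `h` is
the Hamming distance for LBP bit codes and the Euclidean distance otherwise.

With `H_p` (S × N_p) collecting per-scale distance vectors of within-positive
pairs and `H_b` (S × N_b) those of positive-versus-negative pairs — pairs are
drawn within a slice, never across slices — the intra- and inter-class
distance kernels are `S_p = H_p H_pᵀ` and `S_b = H_b H_bᵀ`, and the ideal
weights maximize the discriminant ratio `wᵀ S_b w / wᵀ S_p w` under
box/simplex constraints.  The implemented solver uses the least-squares
reformulation with `R_pᵀ R_p` the Cholesky factorization of `S_p`:

    min_{a, w≥0} ‖H_bᵀ R_p⁻¹ − H_bᵀ w aᵀ‖²_F + η ‖w‖₁ ,   ‖w‖₂² = 1,

alternating two exact steps:

* **w-step** — a LASSO/ridge problem
  `min_{w≥0} ‖H_bᵀR_p⁻¹a − H_bᵀw‖² + α‖w‖² + η‖w‖₁`.  With `w ≥ 0` the ℓ1
  term is linear, so this is the nonnegative quadratic program
  `½wᵀQw + cᵀw`, `Q = 2(S_b + αI)`, `c = η·1 − 2 S_b R_p⁻¹ a`, solved
  exactly by block principal pivoting (with the standard shrinking-exchange
  anti-cycling backup).  Only the S × S kernels enter, so the step is O(S³).
* **a-step** — the closed form `a = R_p⁻ᵀ S_b w / sqrt(wᵀ S_b S_b w)`,
  implemented exactly as written.  Note its denominator is `‖S_b w‖₂`, which
  does not rescale `a` to unit norm; the exact unit-norm minimizer direction
  is available behind `update_a(..., normalize=True)` (default off).
  Monotone descent of the reformulated objective is guaranteed only with
  the normalized variant; with the default, descent holds in practice on
  the fixtures tested but is not a theorem.

Iteration starts from uniform `w = 1/S`, stops at relative w-change < 1e-6
or 100 sweeps, and rescales the result to unit L2 norm.  Scales with
`w_s ≥ σ·max(w)` are selected; the selected set always contains the argmax
and grows as σ decreases.  Weights are learned independently per family.

Degenerate cases: a ridge `1e-8 · trace(S_p)/S` is added to `S_p` before the
Cholesky factorization so `R_p` exists even when all positives coincide; if
no scale carries between-class signal (`S_b w = 0`) the learner returns
uniform weights with `fallback_uniform=True`.

A genuinely flat case is worth knowing about: when between-class distances
are distributed identically to within-class ones (nothing discriminates,
e.g. the kernel fixture at `gap = 1`), the whitened ratio is flat in *every*
direction and the converged `w` is a noise-determined vertex rather than the
uniform vector.  Exchangeability then shows up distributionally — over many
draws no scale is preferred — not within a single realization.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| α (`alpha`) | 0.1 | ridge controller of the w-step |
| η (`eta`, alias `mu`) | 0.001 | ℓ1 sparsity controller |
| σ (`sigma`) | 0.3 | selection threshold, fraction of max weight |
| scale grid | 3, 5, 7 | odd window sides; up to nine scales (…, 25) for high-resolution imagery |
| `rSize`, `reqStr` | 8, 0.01 | SLIC nominal superpixel size / regularization |
| trees | 50 | Random Forest size |
| LBP bits | 8 | ring neighbors per code |
| Gabor angles | 0°, 90°, 180° | filter-bank orientations |
| PHOW length | 128 | 4×4 spatial bins × 8 orientations |
| Haralick | 14 stats, 32 gray levels | per-window GLCM statistics |
| `pairs_per_slice` | 2000 | sampled pairs per kind per slice for the kernels |

## Feature extraction conventions

* Borders: every extractor reflect-pads by the largest window radius;
  coordinates are 0-based row-major.  RGB input is converted to grayscale by
  luminance (0.299 R + 0.587 G + 0.114 B).
* **LBP**: bit = 1 when the bilinearly interpolated ring neighbor is ≥ the
  center (ties → 1), making codes invariant to constant intensity shifts.
  Plain codes by default; a flag maps each code to its minimal cyclic
  rotation (rotation invariance).  The variant choice is configuration, not
  a fixed truth.
* **Gabor**: window side k ⇒ wavelength λ = k, envelope σ_g = 0.5·λ, support
  k × k; kernels are DC-corrected to exactly zero mean (flat patches give a
  zero response); the descriptor holds one complex-response magnitude per
  orientation.  The frequency–scale mapping is likewise configuration-level.
* **Haralick**: each window is min–max quantized to 32 levels; a symmetric
  normalized GLCM is built per distance-1 offset (0°, 45°, 90°, 135°); the
  14 classic statistics use natural logarithms and are averaged over
  offsets.  Undefined correlation-type statistics (single-level windows,
  vanishing marginal entropy, fewer than two occupied levels for the maximal
  correlation coefficient) are defined as 0, never NaN.  The maximal
  correlation coefficient is computed as the second-largest eigenvalue of
  the symmetric similarity `Dx^{-1/2} P Dy^{-1} Pᵀ Dx^{-1/2}`, batched over
  windows.
* **PHOW**: scale k ⇒ spatial bin size m = ⌈k/4⌉; 4×4 flat spatial bins of
  8-bin orientation histograms with linear soft assignment; descriptors are
  L2-normalized, all-zero below gradient energy 1e-10.  No 0.2-clipping
  renormalization is applied.

## Detection pipeline

Superpixels come from SLIC (spatially regularized k-means); the
regularizer scale is implementation-specific, so `reqStr` maps to skimage's
compactness as `100·reqStr` on a [0,1]-normalized image, making the default
0.01 produce compact regions of ≈ `rSize²` pixels.  Balanced training takes
all lesion pixels, one center pixel per fully-negative superpixel, and
seeded uniform top-up (or center subsampling) to equalize counts.  A 50-tree
Random Forest on the concatenated selected-scale descriptors scores every
pixel of a test image; probabilities are rounded half-up to the eleven
levels {0, 0.1, …, 1} and each superpixel is set to its modal level (ties
break toward the smaller level), an idempotent smoothing.  ROC AUC uses
midrank tie handling and is computed on the unsmoothed map by default, with
a flag for the smoothed map and an optional ROI restriction.

## Synthetic phantoms

Real multi-parametric MRI and digitized histology are not bundled; the
phantom generator provides a controlled stand-in that preserves the parts of
the problem the method actually exercises: a two-class textured image whose
class difference is concentrated at a known, planted window scale.  The
background is an oriented sinusoidal grating with spatial period equal to
the planted scale plus i.i.d. Gaussian noise; inside an elliptical lesion
the grating amplitude is multiplied by `1 + effect_size`.  `effect_size = 0`
yields an image bit-identical to the no-lesion image (the null), and the
detection difficulty decreases monotonically in `effect_size`.

The grating is deliberately weak (amplitude 12 vs. noise std 10 on a 0–255
scale).  Two failure modes of a high-contrast grating drove this choice: the
superpixel segmentation follows the stripes, so center-based negative
sampling oversamples grating extrema, and the reflect-padded border band
carries a conspicuous phase defect — both couple pixel scores to lesion
geometry even in the null.  A residual border effect remains (scores
correlate mildly with border distance because lesions never touch the
border), which inflates null AUC by roughly +0.02–0.03 at 128×128 and more
at smaller sizes; it is a property of exhaustive labeling with reflect
padding, not of the scale learner.

What the phantoms do **not** emulate: anatomical structure, bias fields,
multi-channel acquisition, stain variation, annotation noise, or inter-site
heterogeneity.  Passing phantom tests demonstrates the machinery —
optimizer correctness, scale recovery, cost reduction at preserved accuracy
— not clinical performance.

The kernel fixture (`generate_kernel_fixture`) bypasses image space: H_p
entries are |N(1, 0.1)|, H_b rows have mean `gap` at the planted scale and 1
elsewhere (relative spread 0.1), exercising the optimizer directly.

## Problem sizes used in the shipped checks

End-to-end checks run on 128×128 slices (10 train / 5 test, the 3/5/7 scale
grid); null calibration on 10 seeds of 3 train / 2 test slices at 128×128;
scale-recovery and monotonicity properties on 64×64 slices.  These sizes
were chosen as the smallest at which the effects of interest are stable
across seeds.

## Known limitations

* Criterion-level AUCs on clinical data are not reproducible here; all
  quantitative checks are on synthetic phantoms.
* The alternating solver is exact per step but, like any alternating
  scheme, only guaranteed to reach a stationary point of the biconvex
  objective.
* Haralick extraction dominates runtime (batched eigendecompositions for
  the 14th statistic); exhaustive labeling of megapixel histology would
  want tiling.
* The per-slice pair sample (2000 per kind) is a variance/cost trade-off;
  very small slices fall back to exhaustive enumeration of pairs.
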