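# Methods

## Problem and pipeline

The package classifies discrete morphs of a species from grayscale images of
single specimens (one wing, one abdomen per image). The pipeline is
preprocess → (augment) → descriptor extraction → one-vs-one linear SVM →
replicated cross-validated evaluation. Linear kernels are used throughout:
HOG/LBP vectors are high-dimensional (10³–10⁴) relative to typical sample
sizes (10²), where linear decision boundaries already separate well and
nonlinear kernels mostly add variance.

## Preprocessing

Images are converted to 8-bit grayscale with BT.601 luma weights
(0.299, 0.587, 0.114), rounded to the nearest integer; alpha channels are
ignored, 16-bit input is divided down to 8 bits. Brightness/contrast uses
`out = clip(g·(in − 128) + 128 + b)` with `g = (100 + contrast)/100`,
`contrast ∈ [−100, 100]`: a monotone linear map pivoted at mid-gray that is
the identity at (0, 0). Photo-editor parameters of the same name vary by
vendor; parity with any particular editor is not claimed. Coordinates are
0-based row-major; crop windows are half-open.

Dataset validation warns (never raises) when a class has fewer than 10
samples or when the largest/smallest class-size ratio reaches 5 — below
these, the one-vs-one SVMs for the small class become unreliable.

## Augmentation

All stochastic ops work on unit-scale intensities and requantize by
round-half-up. Gaussian noise draws a fresh mean from U(0.1, 0.2) and
variance from U(0.02, 0.05) per generated copy; the contrast stretch draws
input limits low ~ U(0.0, 0.1), high ~ U(0.9, 1.0) and maps [low, high] →
[0, 1] with clipping; the averaging filter is the constant 3×3 kernel with
zero padding (replicate padding available via `pad="replicate"`); flips are
applied with probability ½ each so copies differ. Rotation and color jitter
are not implemented: the pipeline is grayscale, and no rotation scheme is
part of the two preset recipes.

One geometry decision deserves note: a random crop (e.g. 256→224) shrinks
the augmented copies, but a descriptor matrix needs one image size. When
`random_crop` is in the op list, `augment_dataset` center-crops the retained
originals to the crop output size, and `cross_validate` applies the same
center crop to held-out folds (`conform_to_spec`). Descriptor geometry is
therefore defined by the crop output size whenever cropping is used.

`copies_per_image` defaults to 1; the expansion factor is a free parameter
with no canonical value, and more copies mainly cost training time.

## HOG

Centered differences [−1, 0, 1] on unit-scale intensities with replicate
padding at the borders, so every pixel votes and total histogram mass equals
total gradient magnitude (a conservation law the tests assert). Orientation
is folded to [0°, 180°); each pixel's magnitude is split linearly between
the two nearest bin centers (centers at k·20°, circular). Blocks (2×2 cells,
one-cell stride) are normalized by `v/√(‖v‖² + ε²)`, ε = 1e−12, and
concatenated row-major. Plain L2 was chosen over L2-Hys as the simplest
scheme; the dimensional contracts (1,764 at 256², 8,100 at 512²) are
unaffected by the choice. Spatial (trilinear) vote interpolation is not
used — orientation interpolation only. Image sizes not divisible by the
cell size are an error rather than an implicit resize, because silent
geometry changes corrupt the dimensional contract.

## Uniform LBP

Neighbor 0 sits due east, order counterclockwise, bit k weighs 2^k; ties
(neighbor = center) set the bit. Diagonal samples at (±√2/2, ±√2/2) are
bilinearly interpolated; an integer 3×3 variant is available via
`interpolation="nearest"`. The 1-pixel image border produces no code, so
border cells tally slightly fewer pixels — padding would invent texture.
Per-cell 59-bin histograms (58 uniform codes in ascending code order, then
the catch-all) are L2-normalized with a zero-vector guard (unreachable for
cell_size ≥ 3). The bilinear variant agrees exactly with scikit-image's
`local_binary_pattern(..., method="default")` on random images, which the
test suite uses as an independent cross-check; scikit-image is never used in
the pipeline itself.

## One-vs-one ECOC SVM

Coding matrix: columns enumerate pairs (i, j), i < j lexicographically, +1
for class i, −1 for class j. Each binary learner is a soft-margin linear SVM
(sklearn `SVC(kernel="linear")`, tol 1e−6, deterministic) trained only on
its pair's samples, with C = 1 by default — no canonical value exists for
this family of problems, and C is exposed (`--svm-c`). Feature
standardization is off by default because HOG blocks and LBP cell histograms
are already locally normalized. Decoding is majority vote; ties are broken
by the smallest average hinge loss over the coding matrix's non-zero
entries, the standard loss-based ECOC decoding.

Posteriors: each learner's decision values on its own training samples are
calibrated with a Platt sigmoid (Newton iteration with backtracking on the
regularized targets); at predict time the pairwise probabilities are coupled
into one simplex vector by the least-squares consistency method (solve the
quadratic system under Σp = 1, clip, renormalize). This is validated by
property (simplex contract, argmax-consistency with voting, symmetry) rather
than by parity with any specific QP combiner.

Models serialize to a single versioned JSON file carrying the class list,
coding matrix, weights, Platt parameters and a descriptor-config
fingerprint; loading verifies version, shape consistency and (optionally)
the fingerprint, so features extracted under a different configuration are
rejected instead of silently misclassified.

## Evaluation

Folds are stratified by default (protecting classes of 18–19 samples at
k = 10); when the smallest class has fewer than k samples the split falls
back to plain random with a warning. Per replicate the k fold confusion
matrices are summed and one metric set computed from the sum — more robust
than averaging per-fold metrics when folds are tiny. Accuracy is the
main-diagonal proportion. Per-class precision = TP/(TP+FP), recall =
TP/(TP+FN), F1 = 2PR/(P+R) from the one-vs-rest collapse; "overall" values
are unweighted macro means, with undefined entries (empty row/column)
reported as NaN and excluded from the mean with a warning rather than
coerced to 0.

ROC: per class, a one-vs-rest curve is swept over that class's posterior
(sklearn `roc_curve`); the macro curve linearly interpolates each class's
TPR onto the union of all FPR breakpoints and averages — without a common
grid the "mean of the binary curves" is ill-defined. AUC is trapezoidal.
The `roc_experiment` protocol halves the samples at random, augments the
training half, calibrates, and scores the held-out half.

Augmentation always runs inside the CV loop on training folds only. Whether
augmenting before or after fold assignment matters: augmenting first leaks
near-copies of test images into training and inflates accuracy, so the
leakage-free ordering is enforced by construction.

## Synthetic data generator

The generator stands in for specimen photographs with the two statistical
structures the descriptors target, not with photorealistic renderings:

* pattern regime — sinusoidal stripe fields at class-specific orientations
  (evenly spaced over [0°, 180°)) with random phase, ±15% frequency jitter
  and 3 random quadratic dark strokes per image (vein-like distractors);
  `separation` s sets the orientation jitter SD to 25°·(1−s).
* texture regime — Gaussian-smoothed white noise with class-specific
  correlation length, geometrically spaced (σ = 0.6·4^(frac·s) for class
  fraction frac ∈ [0, 1]) because radius-1 LBP resolves granularity best at
  sub-pixel-to-few-pixel scales, plus class-specific dark-dot density
  (0.002 + 0.015·s·(1−frac)).

`noise_sd` adds label-independent pixel noise before quantization. The
benchmark suite reproduces the two study-shaped designs: a 5-class 256×256
pattern set with counts (77, 56, 60, 18, 19) and a 3-class 512×512 texture
set with counts (19, 42, 38), so small-class recall degradation can be
studied qualitatively.

What passing tests on these fixtures shows: the descriptors, classifier and
evaluation machinery recover class structure that is genuinely in the
images, the augmentation direction is right on noise-degraded data, and the
whole pipeline is deterministic under a seed. What it does not show:
performance on real specimen images, whose within-class variation
(illumination, pose, damage, developmental variation) is far richer than
orientation jitter and pixel noise; published accuracies on real datasets
are not reproducible from synthetic stand-ins and are not claimed.

## Problem sizes in the test suite

Unit and acceptance tests run on 64–128 px images with proportionally
smaller descriptor cells (16–32 px) and 5–10-fold CV over 30–50 images with
1–2 replicates — the same geometry ratios as the full-scale configurations
at a fraction of the arithmetic. The dimensional contracts (1,764 / 8,100 /
3,776 / 11,876) are always exercised at full image size, since they are the
point. The augmentation-direction experiment uses the pattern fixture at
noise_sd 0.6 (baseline accuracy ≈ 0.91, leaving headroom in both
directions) over 10 seeds.

## Known limitations

* Brightness/contrast parity with specific photo editors, and bit-level
  parity with other HOG/LBP/ECOC implementations (interpolation internals,
  normalization variants, QP posterior combiners), are out of scope; all
  such choices are documented above and pinned by tests against independent
  oracles instead.
* No rotation-invariant LBP, multi-scale descriptors, nonlinear kernels, or
  hyperparameter search.
* `kfold_split` guarantees stratification within ±1 sample only when the
  class sizes allow it; extremely small classes fall back to random splits.
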