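# morphsvm

Classification of complex morphological characters — wing patterns, body
textures and similar cuticular phenotypes — from grayscale images of
individual specimens, built for taxonomists and evolutionary biologists who
need to sort hundreds of photographed or photoscanned individuals into
discrete morphs without training a deep network on a small dataset.

## Method

Each 8-bit grayscale image is described by a fixed-length feature vector
built from one or both of:

* **HOG** (histogram of oriented gradients): per-pixel gradient magnitudes
  are binned by unsigned orientation (9 bins over [0°, 180°)) within
  square cells (default 32×32 px), and 2×2-cell blocks sliding at one-cell
  stride are L2-normalized and concatenated. On a 256×256 image this gives
  a 1,764-dimensional vector; on 512×512, 8,100. Captures edge and
  pattern structure.
* **Uniform LBP** (local binary patterns): each pixel is coded by
  thresholding its 8 circular radius-1 neighbors against the center
  (bit_k = 1 iff neighbor_k ≥ center). Codes with ≤2 circular bit
  transitions ("uniform") get individual histogram bins, all others share
  one catch-all — 59 bins instead of 256. Per-cell (default 64×64 px)
  histograms are L2-normalized and concatenated: 3,776 dimensions on a
  512×512 image, 11,876 when concatenated after the HOG vector. Captures
  micro-texture such as pilosity.

Classification uses a **one-vs-one multiclass linear SVM**: for *n* classes,
*n*(*n*−1)/2 binary soft-margin linear SVMs (one per class pair) are combined
through an error-correcting output code design; prediction is by majority
vote with hinge-loss decoding as the tie-break. Per-learner Platt sigmoids
plus pairwise coupling yield posterior class probabilities for ROC analysis.

Small datasets are expanded by **label-preserving augmentation** (random
crop, flips, Gaussian noise with mean ~ U(0.1, 0.2) and variance
~ U(0.02, 0.05) on the unit intensity scale, random contrast stretch with
limits U(0.0, 0.1)/U(0.9, 1.0), 3×3 averaging filter), applied inside the
cross-validation loop to training folds only.

Evaluation follows a replicated stratified k-fold protocol (default 20
replicates of 10-fold CV): per replicate the fold confusion matrices (rows =
true, columns = predicted) are summed, and accuracy, per-class
precision/recall/F1 and their unweighted macro means are reported with
across-replicate mean and SD, plus macro-averaged one-vs-rest ROC/AUC.

## Worked example

```python
from morphsvm import FixtureSpec, make_dataset, cross_validate, AugmentSpec
from morphsvm.config import PipelineConfig

# noisy synthetic wing-pattern dataset: 3 morphs x 10 images, 64x64 px
ds = make_dataset(FixtureSpec(regime="pattern", n_classes=3, n_per_class=10,
                              image_size=(64, 64), separation=0.8,
                              noise_sd=0.6, seed=0))
fn, _ = PipelineConfig(descriptor="hog", hog_cell=16).feature_extractor()

plain = cross_validate(ds, fn, k=5, replicates=5, seed=0)
aug = cross_validate(ds, fn, k=5, replicates=5, seed=0,
                     augment_spec=AugmentSpec(ops=("gaussian_noise",
                                                   "random_contrast"),
                                              copies_per_image=2))
print(f"accuracy without augmentation: {plain.mean_accuracy:.4f} (sd {plain.sd_accuracy:.4f})")
print(f"accuracy with augmentation:    {aug.mean_accuracy:.4f} (sd {aug.sd_accuracy:.4f})")
```

prints

```
accuracy without augmentation: 0.9133 (sd 0.0183)
accuracy with augmentation:    0.9400 (sd 0.0435)
```

i.e. on pixel-noise-degraded images, expanding each training fold with two
noise/contrast-jittered copies per image recovers roughly a third of the
lost accuracy; on the noiseless version of the same fixture the classifier
is already perfect (accuracy 1.0000) and augmentation has nothing to add.

## Command line

```bash
morphsvm fixtures --regime pattern --n-classes 3 --out data/        # synthetic demo data
morphsvm preprocess --in raw/ --labels labels.csv --out pre/ --brightness 10 --contrast -50
morphsvm augment --in pre/ --labels pre/labels.csv --out aug/ --preset butterfly --copies 2
morphsvm extract --in pre/ --labels pre/labels.csv --out features.csv --descriptor hog+lbp
morphsvm train --features features.csv --out model.json
morphsvm predict --model model.json --features features.csv --out predictions.csv
morphsvm cv --in pre/ --labels pre/labels.csv --out run/ --preset butterfly
morphsvm roc --in pre/ --labels pre/labels.csv --out roc.csv --plot roc.png
```

Two presets bundle the worked configurations: `butterfly` (256×256 images,
HOG only, crop+noise+contrast augmentation) and `spider` (512×512, HOG +
LBP, crop+flip+filter augmentation).

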