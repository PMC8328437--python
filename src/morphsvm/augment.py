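"""Label-preserving data augmentation for small image training sets.

Every stochastic operation works on the unit intensity scale [0, 1]
(8-bit input is divided by 255 and requantized round-half-up on the way
out) and takes an explicit ``numpy.random.Generator`` so that an entire
augmentation stream is reproducible from one seed.

Two named presets mirror the two study designs:

* ``butterfly`` — random crop + Gaussian noise + random contrast: wing
  patterns tolerate intensity distortion, so aggressive augmentation pays.
* ``spider`` — random crop + horizontal/vertical flips + 3x3 averaging
  filter: micro-texture is fragile under noise/contrast changes, so only
  geometry-preserving-texture ops are used.

When ``random_crop`` is among the ops, the retained originals (and any
held-out evaluation images, via :func:`conform_to_spec`) are center-cropped
to ``crop_out_size`` so every image in the expanded set shares one geometry
— the descriptor stage requires a single image size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import convolve

from .dataset import LabeledImageSet, check_gray_image

VALID_OPS = (
    "random_crop",
    "hflip",
    "vflip",
    "gaussian_noise",
    "random_contrast",
    "average_filter",
)


class AugmentConfigError(ValueError):
    pass


def _to_unit(img: np.ndarray) -> np.ndarray:
    return img.astype(np.float64) / 255.0


def _to_uint8(unit: np.ndarray) -> np.ndarray:
    # round half up, matching the quantization used everywhere else
    return np.floor(np.clip(unit, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


@dataclass
class AugmentSpec:
    """Recipe for expanding a training set.

    ops : ordered list of operation names from :data:`VALID_OPS`.
    crop_out_size : (h, w) output of random_crop.
    noise_mean_range / noise_var_range : per-copy Gaussian noise mean and
        variance drawn uniformly from these unit-scale intervals.
    contrast_low_range / contrast_high_range : unit-scale input limits for
        the random contrast stretch.
    filter_size : averaging-filter kernel, odd in both dimensions.
    copies_per_image : synthetic variants appended per original.
    seed : RNG seed for the whole stream.
    """

    ops: tuple[str, ...] = ("random_crop", "gaussian_noise", "random_contrast")
    crop_out_size: tuple[int, int] = (224, 224)
    noise_mean_range: tuple[float, float] = (0.1, 0.2)
    noise_var_range: tuple[float, float] = (0.02, 0.05)
    contrast_low_range: tuple[float, float] = (0.0, 0.1)
    contrast_high_range: tuple[float, float] = (0.9, 1.0)
    filter_size: tuple[int, int] = (3, 3)
    copies_per_image: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for op in self.ops:
            if op not in VALID_OPS:
                raise AugmentConfigError(f"unknown augmentation op '{op}'")
        for name in ("noise_mean_range", "noise_var_range",
                     "contrast_low_range", "contrast_high_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise AugmentConfigError(
                    f"{name} must satisfy 0 <= low <= high <= 1, got ({lo}, {hi})"
                )
        if self.copies_per_image < 0:
            raise AugmentConfigError("copies_per_image must be >= 0")
        if any(s % 2 == 0 or s < 1 for s in self.filter_size):
            raise AugmentConfigError(
                f"averaging filter size must be odd, got {self.filter_size}"
            )


PRESETS: dict[str, AugmentSpec] = {
    "butterfly": AugmentSpec(
        ops=("random_crop", "gaussian_noise", "random_contrast"),
        crop_out_size=(224, 224),
    ),
    "spider": AugmentSpec(
        ops=("random_crop", "hflip", "vflip", "average_filter"),
        crop_out_size=(448, 448),
    ),
}


def get_preset(name: str, **overrides) -> AugmentSpec:
    if name not in PRESETS:
        raise AugmentConfigError(
            f"unknown preset '{name}'; available: {sorted(PRESETS)}"
        )
    return replace(PRESETS[name], **overrides)


def random_crop(
    img: np.ndarray, out_size: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Crop a window of *out_size*, its offset uniform over valid positions."""
    img = check_gray_image(img)
    oh, ow = out_size
    if oh > img.shape[0] or ow > img.shape[1]:
        raise AugmentConfigError(
            f"crop size {out_size} exceeds image size {img.shape}"
        )
    top = int(rng.integers(0, img.shape[0] - oh + 1))
    left = int(rng.integers(0, img.shape[1] - ow + 1))
    return img[top : top + oh, left : left + ow].copy()


def center_crop(img: np.ndarray, out_size: tuple[int, int]) -> np.ndarray:
    img = check_gray_image(img)
    oh, ow = out_size
    if oh > img.shape[0] or ow > img.shape[1]:
        raise AugmentConfigError(
            f"crop size {out_size} exceeds image size {img.shape}"
        )
    top = (img.shape[0] - oh) // 2
    left = (img.shape[1] - ow) // 2
    return img[top : top + oh, left : left + ow].copy()


def add_gaussian_noise(
    img: np.ndarray,
    mean_range: tuple[float, float],
    var_range: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Add i.i.d. N(m, v) pixel noise, m ~ U(mean_range), v ~ U(var_range).

    Operates on the unit intensity scale; output clipped to [0, 1] and
    requantized to 8 bit.
    """
    img = check_gray_image(img)
    m = rng.uniform(*mean_range)
    v = rng.uniform(*var_range)
    noise = rng.normal(m, np.sqrt(v), size=img.shape)
    return _to_uint8(_to_unit(img) + noise)


def random_contrast(
    img: np.ndarray,
    low_range: tuple[float, float],
    high_range: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Stretch unit-scale intensities [low, high] -> [0, 1] with clipping.

    low ~ U(low_range), high ~ U(high_range); intensities below low map to
    0 and above high to 1 (imadjust-style limits).
    """
    img = check_gray_image(img)
    low = rng.uniform(*low_range)
    high = rng.uniform(*high_range)
    if high <= low:
        raise AugmentConfigError(
            f"contrast limits degenerate: low={low:.3f} >= high={high:.3f}"
        )
    return _to_uint8((_to_unit(img) - low) / (high - low))


def flip(img: np.ndarray, axis: str) -> np.ndarray:
    """Mirror about the named axis ('horizontal' swaps left/right)."""
    img = check_gray_image(img)
    if axis in ("horizontal", "h"):
        return img[:, ::-1].copy()
    if axis in ("vertical", "v"):
        return img[::-1, :].copy()
    raise AugmentConfigError(f"axis must be 'horizontal' or 'vertical', got '{axis}'")


def average_filter(
    img: np.ndarray, size: tuple[int, int] = (3, 3), pad: str = "zero"
) -> np.ndarray:
    """Convolve with the constant 1/(h*w) kernel.

    Zero padding by default (the convolution-mode behaviour of the classic
    MATLAB call this mirrors); ``pad='replicate'`` replicates the border.
    """
    img = check_gray_image(img)
    kh, kw = size
    if kh % 2 == 0 or kw % 2 == 0:
        raise AugmentConfigError(f"filter size must be odd in both dims, got {size}")
    kernel = np.full((kh, kw), 1.0 / (kh * kw))
    mode = "constant" if pad == "zero" else "nearest"
    out = convolve(_to_unit(img), kernel, mode=mode, cval=0.0)
    return _to_uint8(out)


def _augment_one(img: np.ndarray, spec: AugmentSpec, rng: np.random.Generator) -> np.ndarray:
    out = img
    for op in spec.ops:
        if op == "random_crop":
            out = random_crop(out, spec.crop_out_size, rng)
        elif op == "hflip":
            if rng.random() < 0.5:
                out = flip(out, "horizontal")
        elif op == "vflip":
            if rng.random() < 0.5:
                out = flip(out, "vertical")
        elif op == "gaussian_noise":
            out = add_gaussian_noise(out, spec.noise_mean_range, spec.noise_var_range, rng)
        elif op == "random_contrast":
            out = random_contrast(out, spec.contrast_low_range, spec.contrast_high_range, rng)
        elif op == "average_filter":
            out = average_filter(out, spec.filter_size)
    return out


def conform_to_spec(dataset: LabeledImageSet, spec: AugmentSpec) -> LabeledImageSet:
    """Center-crop a dataset to the geometry the augmented set will have.

    Identity when the spec contains no random_crop. Applied to held-out
    folds so train and test descriptors share one dimensionality.
    """
    if "random_crop" not in spec.ops:
        return dataset
    return LabeledImageSet(
        [center_crop(img, spec.crop_out_size) for img in dataset.images],
        list(dataset.labels),
        list(dataset.filenames),
    )


def augment_dataset(dataset: LabeledImageSet, spec: AugmentSpec) -> LabeledImageSet:
    """Return originals plus ``copies_per_image`` variants per image.

    Labels are preserved; every random parameter is drawn independently per
    variant; the whole stream is reproducible from ``spec.seed``. With
    random_crop in the ops the originals are center-cropped to the common
    output geometry.
    """
    rng = np.random.default_rng(spec.seed)
    base = conform_to_spec(dataset, spec)
    images = list(base.images)
    labels = list(base.labels)
    names = list(base.filenames)
    for i, (img, lab) in enumerate(zip(dataset.images, dataset.labels)):
        for c in range(spec.copies_per_image):
            images.append(_augment_one(img, spec, rng))
            labels.append(lab)
            if names:
                stem = dataset.filenames[i].rsplit(".", 1)[0] if dataset.filenames else f"img_{i:05d}"
                names.append(f"{stem}_aug{c}.png")
    return LabeledImageSet(images, labels, names if names else [])
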