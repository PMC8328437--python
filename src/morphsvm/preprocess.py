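"""Image loading, grayscale conversion, brightness/contrast and cropping.

Both descriptor families consume 8-bit grayscale input, so everything is
converted up front. Brightness/contrast uses a linear map pivoted at
mid-gray (128): ``out = clip(g * (in - 128) + 128 + b, 0, 255)`` with gain
``g = (100 + contrast) / 100`` for contrast in [-100, 100]. This is a
monotone, identity-at-zero reading of photo-editor style parameters; exact
parity with any particular editor is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import LabeledImageSet, check_gray_image

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


class ImageInputError(ValueError):
    """Unreadable or structurally invalid image input."""


class BoundsError(ValueError):
    """A crop window falls outside the image."""


@dataclass
class PreprocessConfig:
    """Deterministic preprocessing settings.

    brightness : additive offset in 8-bit intensity units (may be negative).
    contrast : slope adjustment on a [-100, 100] scale; 0 is identity.
    target_size : optional (height, width) the image is resized to after
        the intensity adjustment (bilinear).
    """

    brightness: float = 0.0
    contrast: float = 0.0
    target_size: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.target_size is not None:
            h, w = self.target_size
            if h <= 0 or w <= 0:
                raise ValueError(f"target_size must be positive, got {self.target_size}")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an RGB(A) or grayscale raster to 8-bit grayscale.

    Uses BT.601 luma weights (0.299, 0.587, 0.114) rounded to the nearest
    integer. Alpha channels are ignored. 16-bit input is rescaled to 8 bit
    by integer division. Grayscale input passes through unchanged (up to
    the 8-bit quantization).
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ImageInputError("empty (zero-size) image")
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)  # 65535 -> 255
    if arr.ndim == 2:
        return arr.astype(np.uint8)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        luma = arr[:, :, :3].astype(np.float64) @ _LUMA
        return np.floor(luma + 0.5).clip(0, 255).astype(np.uint8)
    raise ImageInputError(f"cannot interpret image with shape {arr.shape} as raster")


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file and return it as 8-bit grayscale."""
    from PIL import Image, UnidentifiedImageError

    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise ImageInputError(f"cannot read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise ImageInputError(f"image file {path} decodes to zero pixels")
    try:
        return to_grayscale(arr)
    except ImageInputError as exc:
        raise ImageInputError(f"{path}: {exc}") from exc


def adjust_brightness_contrast(
    img: np.ndarray, brightness: float = 0.0, contrast: float = 0.0
) -> np.ndarray:
    """Linear brightness/contrast adjustment with clipping.

    ``out = clip(g * (in - 128) + 128 + brightness)`` with
    ``g = (100 + contrast) / 100``; (0, 0) is the identity.
    """
    img = check_gray_image(img)
    gain = (100.0 + contrast) / 100.0
    out = gain * (img.astype(np.float64) - 128.0) + 128.0 + brightness
    return np.floor(out + 0.5).clip(0, 255).astype(np.uint8)


def crop(img: np.ndarray, top: int, left: int, height: int, width: int) -> np.ndarray:
    """Extract the half-open window [top, top+height) x [left, left+width)."""
    img = check_gray_image(img)
    if height <= 0 or width <= 0:
        raise BoundsError(f"crop size must be positive, got {height}x{width}")
    if top < 0 or left < 0:
        raise BoundsError(f"crop origin ({top}, {left}) is negative")
    if top + height > img.shape[0]:
        raise BoundsError(
            f"crop bottom {top + height} exceeds image height {img.shape[0]}"
        )
    if left + width > img.shape[1]:
        raise BoundsError(
            f"crop right {left + width} exceeds image width {img.shape[1]}"
        )
    return img[top : top + height, left : left + width].copy()


def resize(img: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to (height, width)."""
    from PIL import Image

    img = check_gray_image(img)
    h, w = target_size
    out = Image.fromarray(img, mode="L").resize((w, h), Image.BILINEAR)
    return np.asarray(out, dtype=np.uint8)


def preprocess_image(img: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Apply the full deterministic preprocessing chain to one image."""
    out = adjust_brightness_contrast(img, cfg.brightness, cfg.contrast)
    if cfg.target_size is not None and tuple(out.shape) != tuple(cfg.target_size):
        out = resize(out, cfg.target_size)
    return out


def preprocess_dataset(dataset: LabeledImageSet, cfg: PreprocessConfig) -> LabeledImageSet:
    return LabeledImageSet(
        [preprocess_image(img, cfg) for img in dataset.images],
        list(dataset.labels),
        list(dataset.filenames),
    )


def validate_dataset(dataset: LabeledImageSet) -> list[str]:
    """Check sample-size guidance and return human-readable warnings.

    Small training classes and strong class imbalance both degrade the
    one-vs-one SVM; the recommended floor is 10 samples per class with a
    largest/smallest class-size ratio below 5. Never raises.
    """
    warnings: list[str] = []
    counts = dataset.class_counts()
    for label in sorted(counts):
        if counts[label] < 10:
            warnings.append(
                f"class '{label}' has only {counts[label]} samples; "
                "at least 10 per class is recommended"
            )
    if counts:
        largest, smallest = max(counts.values()), min(counts.values())
        if smallest > 0 and largest / smallest >= 5:
            warnings.append(
                f"class-size ratio {largest}/{smallest} = {largest / smallest:.2f} "
                ">= 5; a ratio below 5 is recommended"
            )
    return warnings
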