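"""Labeled image collections and the CSV label-table format.

Images are plain 2-D ``numpy.uint8`` arrays (8-bit grayscale, row-major,
0-based coordinates). A :class:`LabeledImageSet` pairs a list of such arrays
with string class labels and optional source filenames; it is the unit that
flows through preprocessing, augmentation and cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class DatasetError(ValueError):
    """Raised for malformed label tables or inconsistent image sets."""


def check_gray_image(img: np.ndarray) -> np.ndarray:
    """Validate that *img* is a 2-D uint8 grayscale image and return it."""
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise DatasetError(f"expected a 2-D image with positive size, got shape {img.shape}")
    if img.dtype != np.uint8:
        raise DatasetError(f"expected uint8 intensities in [0, 255], got dtype {img.dtype}")
    return img


@dataclass
class LabeledImageSet:
    """Images paired with class labels.

    Parameters
    ----------
    images : list of 2-D uint8 arrays
        Grayscale images; sizes may differ between entries.
    labels : list of str
        One class label per image.
    filenames : list of str, optional
        Source filename per image (used by the CLI for traceable output).
    """

    images: list[np.ndarray]
    labels: list[str]
    filenames: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise DatasetError(
                f"{len(self.images)} images but {len(self.labels)} labels"
            )
        if self.filenames and len(self.filenames) != len(self.images):
            raise DatasetError("filenames, when given, must match the image count")
        for img in self.images:
            check_gray_image(img)

    def __len__(self) -> int:
        return len(self.images)

    @property
    def classes(self) -> list[str]:
        """Sorted distinct labels."""
        return sorted(set(self.labels))

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    def subset(self, indices: Iterable[int]) -> "LabeledImageSet":
        idx = list(indices)
        return LabeledImageSet(
            images=[self.images[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            filenames=[self.filenames[i] for i in idx] if self.filenames else [],
        )

    def extend(self, other: "LabeledImageSet") -> "LabeledImageSet":
        """Concatenate two sets (filenames kept only if both carry them)."""
        keep_names = bool(self.filenames) and bool(other.filenames)
        return LabeledImageSet(
            images=self.images + other.images,
            labels=self.labels + other.labels,
            filenames=self.filenames + other.filenames if keep_names else [],
        )


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Read a ``filename,label`` CSV (UTF-8, header required)."""
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    expected = ["filename", "label"]
    if list(df.columns[:2]) != expected:
        raise DatasetError(
            f"label table {path} must start with columns {expected}, got {list(df.columns)}"
        )
    if df["filename"].isna().any() or df["label"].isna().any():
        raise DatasetError(f"label table {path} contains empty filename/label entries")
    return df[expected]


def write_label_table(dataset: LabeledImageSet, path: str | Path) -> None:
    if not dataset.filenames:
        raise DatasetError("dataset has no filenames to write to a label table")
    pd.DataFrame({"filename": dataset.filenames, "label": dataset.labels}).to_csv(
        path, index=False, encoding="utf-8"
    )


def load_image_dir(image_dir: str | Path, labels_csv: str | Path) -> LabeledImageSet:
    """Load every image listed in *labels_csv* from *image_dir*."""
    from .preprocess import load_image  # deferred: avoids an import cycle

    image_dir = Path(image_dir)
    table = read_label_table(labels_csv)
    images, labels, names = [], [], []
    for _, row in table.iterrows():
        images.append(load_image(image_dir / row["filename"]))
        labels.append(row["label"])
        names.append(row["filename"])
    if not images:
        raise DatasetError(f"label table {labels_csv} lists no images")
    return LabeledImageSet(images, labels, names)


def save_image_dir(dataset: LabeledImageSet, out_dir: str | Path) -> None:
    """Write all images as lossless PNG plus a labels.csv into *out_dir*."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not dataset.filenames:
        dataset = LabeledImageSet(
            dataset.images,
            dataset.labels,
            [f"img_{i:05d}.png" for i in range(len(dataset))],
        )
    for img, name in zip(dataset.images, dataset.filenames):
        Image.fromarray(img, mode="L").save(out_dir / name, format="PNG")
    write_label_table(dataset, out_dir / "labels.csv")
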