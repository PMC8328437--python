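"""Declarative pipeline configuration and the end-to-end runner.

A :class:`PipelineConfig` captures every knob of the workflow
(preprocess -> augment -> extract -> train -> evaluate); two named presets
correspond to the two worked study designs. :func:`run_pipeline` executes
the stages against an input directory and writes a self-describing run
directory (the exact config used is serialized next to every artifact).
"""

from __future__ import annotations

import dataclasses
import json
import time
import tomllib
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .augment import PRESETS, AugmentSpec, augment_dataset
from .dataset import load_image_dir
from .evaluation import cross_validate
from .hog import HOGConfig, HOGDescriptor, hog_dim
from .lbp import LBPConfig, LBPDescriptor, lbp_dim
from .preprocess import PreprocessConfig, preprocess_dataset, validate_dataset
from .svm import PairwiseLinearSVM, save_model


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one run."""

    # preprocess
    brightness: float = 0.0
    contrast: float = 0.0
    target_size: tuple[int, int] | None = None
    # augmentation (None disables)
    augment: AugmentSpec | None = None
    # descriptors: "hog", "lbp" or "hog+lbp"
    descriptor: str = "hog"
    hog_cell: int = 32
    hog_block: int = 2
    hog_bins: int = 9
    lbp_cell: int = 64
    # classifier
    svm_c: float = 1.0
    standardize: bool = False
    # evaluation
    k: int = 10
    replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.descriptor not in ("hog", "lbp", "hog+lbp"):
            raise PipelineConfigError(
                f"descriptor must be 'hog', 'lbp' or 'hog+lbp', got '{self.descriptor}'"
            )

    def validate_geometry(self, image_size: tuple[int, int]) -> int:
        """Fail fast on cell-divisibility problems; returns feature dim."""
        dim = 0
        if "hog" in self.descriptor:
            dim += hog_dim(
                HOGConfig(cell_size=self.hog_cell, block_size=self.hog_block,
                          n_bins=self.hog_bins),
                image_size,
            )
        if "lbp" in self.descriptor:
            dim += lbp_dim(LBPConfig(cell_size=self.lbp_cell), image_size)
        return dim

    def feature_extractor(self):
        """Callable list-of-images -> (n, d) feature matrix, plus fingerprint."""
        extractors = []
        if "hog" in self.descriptor:
            extractors.append(HOGDescriptor(
                cell_size=self.hog_cell, block_size=self.hog_block,
                n_bins=self.hog_bins,
            ))
        if "lbp" in self.descriptor:
            extractors.append(LBPDescriptor(cell_size=self.lbp_cell))

        def feature_fn(images):
            return np.hstack([e.transform(images) for e in extractors])

        fingerprint = {"descriptor": self.descriptor,
                       "parts": [e.fingerprint() for e in extractors]}
        return feature_fn, fingerprint


def presets() -> dict[str, PipelineConfig]:
    """The two worked configurations.

    ``butterfly``: 256x256 wing-pattern images, HOG only (cell 32,
    2x2-cell blocks, 9 bins), crop+noise+contrast augmentation.
    ``spider``: 512x512 body-texture images, HOG + uniform LBP (cell 64),
    crop+flip+averaging-filter augmentation.
    """
    return {
        "butterfly": PipelineConfig(
            brightness=10, contrast=-50, target_size=(256, 256),
            augment=PRESETS["butterfly"], descriptor="hog",
        ),
        "spider": PipelineConfig(
            target_size=(512, 512),
            augment=PRESETS["spider"], descriptor="hog+lbp",
        ),
    }


def get_preset(name: str) -> PipelineConfig:
    p = presets()
    if name not in p:
        raise PipelineConfigError(f"unknown preset '{name}'; available: {sorted(p)}")
    return p[name]


def _config_to_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["version"] = __version__
    return d


def config_from_toml(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a flat TOML file.

    Recognized keys mirror the dataclass fields; an ``[augment]`` table
    builds an :class:`AugmentSpec`.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    aug = raw.pop("augment", None)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineConfigError(f"unknown config keys in {path}: {sorted(unknown)}")
    if "target_size" in raw and raw["target_size"] is not None:
        raw["target_size"] = tuple(raw["target_size"])
    cfg = PipelineConfig(**raw)
    if aug is not None:
        for key in ("ops", "crop_out_size", "noise_mean_range", "noise_var_range",
                    "contrast_low_range", "contrast_high_range", "filter_size"):
            if key in aug:
                aug[key] = tuple(aug[key])
        cfg = replace(cfg, augment=AugmentSpec(**aug))
    return cfg


def _log(quiet: bool, stage: str, message: str, t0: float) -> None:
    if not quiet:
        print(f"[{stage}] {message} (elapsed {time.perf_counter() - t0:.2f}s)")


def run_pipeline(
    cfg: PipelineConfig,
    image_dir: str | Path,
    labels_csv: str | Path,
    out_dir: str | Path,
    quiet: bool = False,
) -> Path:
    """Execute preprocess -> (augment) -> extract -> train -> cv.

    Writes into *out_dir*: the serialized config, the feature matrix, the
    trained model, the CV metrics table and summed confusion matrix.
    Returns the run directory path.
    """
    t0 = time.perf_counter()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(
        json.dumps(_config_to_dict(cfg), indent=2, default=str), encoding="utf-8"
    )

    dataset = load_image_dir(image_dir, labels_csv)
    _log(quiet, "load", f"{len(dataset)} images, {len(dataset.classes)} classes", t0)
    for warning in validate_dataset(dataset):
        print(f"[validate] WARNING: {warning}")

    pre = PreprocessConfig(brightness=cfg.brightness, contrast=cfg.contrast,
                           target_size=cfg.target_size)
    dataset = preprocess_dataset(dataset, pre)
    _log(quiet, "preprocess", f"brightness={cfg.brightness} contrast={cfg.contrast}", t0)

    work_size = dataset.images[0].shape
    if cfg.augment is not None and "random_crop" in cfg.augment.ops:
        work_size = cfg.augment.crop_out_size
    dim = cfg.validate_geometry(tuple(work_size))
    _log(quiet, "extract", f"descriptor={cfg.descriptor}, {dim} dims", t0)

    feature_fn, fingerprint = cfg.feature_extractor()

    # cross-validated evaluation (augmentation handled inside the folds)
    result = cross_validate(
        dataset, feature_fn, k=cfg.k, replicates=cfg.replicates, seed=cfg.seed,
        augment_spec=cfg.augment, svm_c=cfg.svm_c, standardize=cfg.standardize,
    )
    summary = result.summary()
    _log(quiet, "cv",
         f"{cfg.replicates}x{cfg.k}-fold accuracy "
         f"{summary['accuracy_mean']:.4f} ({summary['accuracy_sd']:.4f})", t0)

    rows = []
    for ci, c in enumerate(result.classes):
        rows.append({
            "class": c,
            "precision": float(np.nanmean([r.precision[ci] for r in result.replicates])),
            "recall": float(np.nanmean([r.recall[ci] for r in result.replicates])),
            "f1": float(np.nanmean([r.f1[ci] for r in result.replicates])),
        })
    rows.append({
        "class": "overall",
        "precision": summary["overall_precision_mean"],
        "recall": summary["overall_recall_mean"],
        "f1": summary["overall_f1_mean"],
    })
    pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False)
    pooled = sum(r.confusion for r in result.replicates)
    pd.DataFrame(pooled, index=result.classes, columns=result.classes).to_csv(
        out_dir / "confusion.csv"
    )
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2),
                                          encoding="utf-8")

    # final model on the full (augmented) dataset
    train = dataset
    if cfg.augment is not None:
        train = augment_dataset(dataset, replace(cfg.augment, seed=cfg.seed))
    X = feature_fn(train.images)
    clf = PairwiseLinearSVM(C=cfg.svm_c, standardize=cfg.standardize)
    clf.fit(X, np.asarray(train.labels), fingerprint=fingerprint)
    save_model(clf, out_dir / "model.json")
    _log(quiet, "train", f"final model on {len(train)} images saved", t0)
    return out_dir
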