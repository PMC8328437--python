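"""Deterministic synthetic image datasets for exercising the pipeline.

Two regimes mirror the two kinds of morphological character the pipeline
targets:

* ``pattern`` — oriented stripe fields plus curved dark "vein" strokes:
  classes differ by stripe orientation (evenly spaced over [0°, 180°)),
  which the HOG descriptor separates. Emulates wing-pattern morphs.
* ``texture`` — stochastic micro-texture: classes differ in correlation
  length (smoothing scale of a noise field) and dark-dot density, which
  the uniform-LBP histograms separate. Emulates body-texture morphs
  (hairless vs sparse vs dense pilosity).

``separation`` in [0, 1] scales how distinct the class templates are
(1 = maximally distinct); ``noise_sd`` adds label-independent Gaussian
pixel noise on the unit intensity scale. Everything is driven by one
seeded generator: identical spec + seed reproduces the dataset bit for
bit; no files or network are touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .dataset import LabeledImageSet


class FixtureConfigError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Parameters of a generated dataset.

    regime : 'pattern' or 'texture'.
    n_classes : number of classes (>= 2).
    n_per_class : samples per class, or per-class counts via
        :func:`make_pattern_classes`/:func:`make_texture_classes` ``counts``.
    image_size : (height, width) of every image.
    separation : between-class distinctness in [0, 1].
    noise_sd : sd of additive unit-scale Gaussian pixel noise.
    seed : RNG seed.
    """

    regime: str = "pattern"
    n_classes: int = 3
    n_per_class: int = 10
    image_size: tuple[int, int] = (128, 128)
    separation: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("pattern", "texture"):
            raise FixtureConfigError(f"unknown regime '{self.regime}'")
        if self.n_classes < 2:
            raise FixtureConfigError("n_classes must be >= 2")
        if self.n_per_class < 1:
            raise FixtureConfigError("n_per_class must be >= 1")
        if not (0.0 <= self.separation <= 1.0):
            raise FixtureConfigError("separation must lie in [0, 1]")
        if self.noise_sd < 0:
            raise FixtureConfigError("noise_sd must be >= 0")
        h, w = self.image_size
        if h < 8 or w < 8:
            raise FixtureConfigError("image_size must be at least 8x8")


def _quantize(unit: np.ndarray) -> np.ndarray:
    return np.floor(np.clip(unit, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


def _vein_strokes(img: np.ndarray, rng: np.random.Generator, n_strokes: int = 3) -> None:
    """Stamp dark curved strokes (quadratic Bezier paths) in place."""
    h, w = img.shape
    for _ in range(n_strokes):
        pts = rng.uniform([0, 0], [h - 1, w - 1], size=(3, 2))
        t = np.linspace(0.0, 1.0, 4 * max(h, w))[:, None]
        curve = ((1 - t) ** 2 * pts[0] + 2 * (1 - t) * t * pts[1] + t**2 * pts[2])
        rr = np.clip(np.round(curve[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(curve[:, 1]).astype(int), 0, w - 1)
        img[rr, cc] = np.minimum(img[rr, cc], 0.15)


def _pattern_image(
    theta_deg: float,
    size: tuple[int, int],
    separation: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    h, w = size
    # orientation jitter grows as separation shrinks (classes blur together)
    jitter_sd = 25.0 * (1.0 - separation)
    theta = np.radians(theta_deg + rng.normal(0.0, jitter_sd))
    freq = 6.0 * (1.0 + 0.15 * rng.uniform(-1, 1))
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    u = (xx * np.cos(theta) + yy * np.sin(theta)) / max(h, w)
    img = 0.5 + 0.4 * np.sin(2 * np.pi * freq * u + phase)
    _vein_strokes(img, rng)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return _quantize(img)


def _texture_image(
    class_idx: int,
    n_classes: int,
    size: tuple[int, int],
    separation: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    h, w = size
    # class-specific correlation length and dot density; separation pulls
    # the per-class values apart, 0 collapses them onto the common mean
    frac = class_idx / max(n_classes - 1, 1)
    # geometric spacing: radius-1 LBP resolves granularity differences best
    # at sub-pixel to few-pixel correlation lengths
    sigma = 0.6 * (4.0**(frac * separation)) * (1.0 + 0.05 * rng.uniform(-1, 1))
    density = 0.002 + separation * 0.015 * (1.0 - frac)
    base = gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=sigma)
    sd = base.std()
    img = 0.5 + 0.25 * base / (sd if sd > 0 else 1.0)
    n_dots = rng.poisson(density * h * w)
    if n_dots:
        rr = rng.integers(0, h, size=n_dots)
        cc = rng.integers(0, w, size=n_dots)
        img[rr, cc] = 0.0
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return _quantize(img)


def _counts(spec: FixtureSpec, counts: Sequence[int] | None) -> list[int]:
    if counts is None:
        return [spec.n_per_class] * spec.n_classes
    if len(counts) != spec.n_classes:
        raise FixtureConfigError(
            f"counts has {len(counts)} entries for {spec.n_classes} classes"
        )
    if any(c < 1 for c in counts):
        raise FixtureConfigError("all class counts must be >= 1")
    return list(counts)


def make_pattern_classes(
    spec: FixtureSpec, counts: Sequence[int] | None = None
) -> LabeledImageSet:
    """Oriented-stripe classes; class c has stripe orientation 180*c/n degrees."""
    if spec.regime != "pattern":
        raise FixtureConfigError(f"spec.regime is '{spec.regime}', expected 'pattern'")
    rng = np.random.default_rng(spec.seed)
    images, labels, names = [], [], []
    for ci, n_c in enumerate(_counts(spec, counts)):
        theta = 180.0 * ci / spec.n_classes
        for s in range(n_c):
            images.append(
                _pattern_image(theta, spec.image_size, spec.separation,
                               spec.noise_sd, rng)
            )
            labels.append(f"morph{ci + 1}")
            names.append(f"pattern_c{ci + 1}_{s:04d}.png")
    return LabeledImageSet(images, labels, names)


def make_texture_classes(
    spec: FixtureSpec, counts: Sequence[int] | None = None
) -> LabeledImageSet:
    """Micro-texture classes differing in granularity and dot density."""
    if spec.regime != "texture":
        raise FixtureConfigError(f"spec.regime is '{spec.regime}', expected 'texture'")
    rng = np.random.default_rng(spec.seed)
    images, labels, names = [], [], []
    for ci, n_c in enumerate(_counts(spec, counts)):
        for s in range(n_c):
            images.append(
                _texture_image(ci, spec.n_classes, spec.image_size,
                               spec.separation, spec.noise_sd, rng)
            )
            labels.append(f"morph{ci + 1}")
            names.append(f"texture_c{ci + 1}_{s:04d}.png")
    return LabeledImageSet(images, labels, names)


def make_dataset(spec: FixtureSpec, counts: Sequence[int] | None = None) -> LabeledImageSet:
    if spec.regime == "pattern":
        return make_pattern_classes(spec, counts)
    return make_texture_classes(spec, counts)


# class counts of the two worked studies: 230 butterflies over five
# wing-pattern morphs, 99 spiders over three body-texture morphs
BUTTERFLY_COUNTS = (77, 56, 60, 18, 19)
SPIDER_COUNTS = (19, 42, 38)


def make_benchmark_suite(seed: int = 0) -> dict[str, LabeledImageSet]:
    """The two standard benchmark fixtures.

    ``butterfly``: 5 pattern classes, 256x256, imbalanced counts
    (77, 56, 60, 18, 19) = 230 images. ``spider``: 3 texture classes,
    512x512, counts (19, 42, 38) = 99 images. The imbalance reproduces the
    small-class regime where recall degradation appears.
    """
    butterfly = make_pattern_classes(
        FixtureSpec(regime="pattern", n_classes=5, n_per_class=1,
                    image_size=(256, 256), separation=1.0, noise_sd=0.02,
                    seed=seed),
        counts=BUTTERFLY_COUNTS,
    )
    spider = make_texture_classes(
        FixtureSpec(regime="texture", n_classes=3, n_per_class=1,
                    image_size=(512, 512), separation=1.0, noise_sd=0.02,
                    seed=seed + 1),
        counts=SPIDER_COUNTS,
    )
    return {"butterfly": butterfly, "spider": spider}
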