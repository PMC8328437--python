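"""Histogram-of-oriented-gradients descriptor (Dalal–Triggs style).

Configuration used throughout the wing-pattern experiments: 32x32-pixel
cells, 2x2-cell blocks sliding with a one-cell stride, 9 unsigned
orientation bins over [0°, 180°). On a 256x256 image this yields
(8-1)^2 blocks * 4 cells * 9 bins = 1764 dimensions; on 512x512, 8100.

Gradients are centered differences [-1, 0, 1] on unit-scale intensities
with replicate padding at the borders, so every pixel contributes a vote
and the total histogram mass equals the total gradient magnitude. Each
pixel's magnitude is split between the two nearest orientation-bin centers
(circular over 180°). Blocks are normalized by v / sqrt(||v||^2 + eps^2)
and concatenated row-major.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import check_gray_image


class HOGConfigError(ValueError):
    pass


@dataclass
class HOGConfig:
    """HOG geometry and binning parameters.

    cell_size : pixels per (square) cell side.
    block_size : cells per block side; blocks overlap at one-cell stride.
    n_bins : orientation bins, evenly spaced over the unsigned range
        [0°, 180°).
    norm_epsilon : stabilizer in the block L2 normalization.
    """

    cell_size: int = 32
    block_size: int = 2
    block_stride: int = 1
    n_bins: int = 9
    norm_epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.cell_size < 2:
            raise HOGConfigError(f"cell_size must be >= 2, got {self.cell_size}")
        if self.block_size < 1:
            raise HOGConfigError(f"block_size must be >= 1, got {self.block_size}")
        if self.block_stride != 1:
            raise HOGConfigError("only a one-cell block stride is supported")
        if self.n_bins < 2:
            raise HOGConfigError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.norm_epsilon <= 0:
            raise HOGConfigError("norm_epsilon must be positive")


def _check_divisible(cfg: HOGConfig, shape: tuple[int, int]) -> tuple[int, int]:
    h, w = shape
    if h % cfg.cell_size or w % cfg.cell_size:
        raise HOGConfigError(
            f"image size {h}x{w} is not divisible by cell_size {cfg.cell_size}; "
            "crop or resize the input to a multiple of the cell size"
        )
    cy, cx = h // cfg.cell_size, w // cfg.cell_size
    if cy < cfg.block_size or cx < cfg.block_size:
        raise HOGConfigError(
            f"cell grid {cy}x{cx} smaller than block_size {cfg.block_size}"
        )
    return cy, cx


def compute_gradients(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel gradient magnitude and unsigned orientation.

    Returns (magnitude, orientation_degrees) with orientation folded into
    [0, 180): a vertical step edge (horizontal gradient) has orientation 0.
    """
    img = check_gray_image(img)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise HOGConfigError(f"image {img.shape} too small for gradients (need >= 3x3)")
    f = img.astype(np.float64) / 255.0
    p = np.pad(f, 1, mode="edge")
    dx = p[1:-1, 2:] - p[1:-1, :-2]
    dy = p[2:, 1:-1] - p[:-2, 1:-1]
    magnitude = np.hypot(dx, dy)
    orientation = np.degrees(np.arctan2(dy, dx)) % 180.0
    return magnitude, orientation


def cell_histograms(
    magnitude: np.ndarray, orientation: np.ndarray, cfg: HOGConfig
) -> np.ndarray:
    """Accumulate per-cell orientation histograms.

    Each pixel votes its gradient magnitude, linearly interpolated between
    the two nearest bin centers (bin centers at k * 180/n_bins, circular
    over 180°). Returns an array of shape (cells_y, cells_x, n_bins).
    """
    cy, cx = _check_divisible(cfg, magnitude.shape)
    bin_width = 180.0 / cfg.n_bins
    pos = orientation / bin_width
    lo = np.floor(pos).astype(np.intp) % cfg.n_bins
    hi = (lo + 1) % cfg.n_bins
    w_hi = pos - np.floor(pos)
    w_lo = 1.0 - w_hi

    rows, cols = np.indices(magnitude.shape)
    cell_r = rows // cfg.cell_size
    cell_c = cols // cfg.cell_size
    hist = np.zeros((cy, cx, cfg.n_bins))
    np.add.at(hist, (cell_r, cell_c, lo), magnitude * w_lo)
    np.add.at(hist, (cell_r, cell_c, hi), magnitude * w_hi)
    return hist


def block_normalize(cells: np.ndarray, cfg: HOGConfig) -> np.ndarray:
    """Slide block_size^2-cell blocks at one-cell stride and L2-normalize.

    Each block's concatenated histograms are divided by
    sqrt(||v||^2 + eps^2); blocks are concatenated row-major.
    """
    cy, cx, n_bins = cells.shape
    b = cfg.block_size
    if cy < b or cx < b:
        raise HOGConfigError(f"cell grid {cy}x{cx} smaller than block size {b}")
    by, bx = cy - b + 1, cx - b + 1
    out = np.empty((by, bx, b * b * n_bins))
    for i in range(by):
        for j in range(bx):
            v = cells[i : i + b, j : j + b, :].reshape(-1)
            out[i, j, :] = v / np.sqrt(v @ v + cfg.norm_epsilon**2)
    return out.reshape(-1)


def hog_dim(cfg: HOGConfig, image_size: tuple[int, int]) -> int:
    """Descriptor length for a given image size."""
    cy, cx = _check_divisible(cfg, image_size)
    b = cfg.block_size
    return (cy - b + 1) * (cx - b + 1) * b * b * cfg.n_bins


def extract_hog(img: np.ndarray, cfg: HOGConfig | None = None) -> np.ndarray:
    """Full HOG descriptor for one image; length equals :func:`hog_dim`."""
    cfg = cfg or HOGConfig()
    magnitude, orientation = compute_gradients(img)
    cells = cell_histograms(magnitude, orientation, cfg)
    return block_normalize(cells, cfg)


class HOGDescriptor(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer: stack of images -> HOG matrix.

    Parameters mirror :class:`HOGConfig`. ``fit`` only records the image
    geometry (``image_size_``, ``n_features_out_``); ``transform`` accepts a
    3-D uint8 array (n, h, w) or a list of 2-D images of equal size.
    """

    def __init__(
        self,
        cell_size: int = 32,
        block_size: int = 2,
        n_bins: int = 9,
        norm_epsilon: float = 1e-12,
    ):
        self.cell_size = cell_size
        self.block_size = block_size
        self.n_bins = n_bins
        self.norm_epsilon = norm_epsilon

    def _config(self) -> HOGConfig:
        return HOGConfig(
            cell_size=self.cell_size,
            block_size=self.block_size,
            n_bins=self.n_bins,
            norm_epsilon=self.norm_epsilon,
        )

    @staticmethod
    def _as_stack(X) -> list[np.ndarray]:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return [X[i] for i in range(X.shape[0])]
        images = list(X)
        if not images:
            raise HOGConfigError("empty image collection")
        return images

    def fit(self, X, y=None):
        images = self._as_stack(X)
        self.image_size_ = tuple(images[0].shape)
        self.n_features_out_ = hog_dim(self._config(), self.image_size_)
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._config()
        images = self._as_stack(X)
        return np.vstack([extract_hog(img, cfg) for img in images])

    def fingerprint(self) -> dict:
        return {
            "descriptor": "hog",
            "cell_size": self.cell_size,
            "block_size": self.block_size,
            "n_bins": self.n_bins,
        }
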