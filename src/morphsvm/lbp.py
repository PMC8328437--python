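"""Uniform local-binary-pattern texture descriptor.

Radius-1, 8-neighbor circular sampling: neighbor 0 sits due east of the
center pixel and subsequent neighbors proceed counterclockwise in 45°
steps; the four diagonal samples at (±√2/2, ±√2/2) are obtained by
bilinear interpolation. Bit k is set when neighbor_k >= center, giving a
code in [0, 255]. Codes whose circular bit string has at most two 0<->1
transitions are "uniform"; there are exactly 58 of them, and every
non-uniform code shares one catch-all bin, for 59 histogram bins total.

The image is tiled into square cells; each cell's 59-bin histogram of the
codes of its interior pixels (a 1-pixel image border produces no code) is
L2-normalized and the cells are concatenated row-major. Rotation-invariant
mappings are deliberately not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import check_gray_image

N_UNIFORM_BINS = 59  # 58 uniform patterns + 1 catch-all


class LBPConfigError(ValueError):
    pass


@dataclass
class LBPConfig:
    """LBP sampling and pooling parameters.

    Radius and neighbor count are fixed at (1, 8) — the 59-bin uniform
    histogram structure is specific to 8 sample points.

    cell_size : pixels per (square) pooling cell side.
    interpolation : 'bilinear' samples the circle exactly; 'nearest' uses
        the integer 3x3 neighborhood instead.
    """

    radius: int = 1
    n_neighbors: int = 8
    cell_size: int = 64
    uniform: bool = True
    rotation_invariant: bool = False
    interpolation: str = "bilinear"

    def __post_init__(self) -> None:
        if self.radius != 1 or self.n_neighbors != 8:
            raise LBPConfigError("only radius=1 with 8 neighbors is supported")
        if self.rotation_invariant:
            raise LBPConfigError("rotation-invariant mapping is not supported")
        if not self.uniform:
            raise LBPConfigError("only the uniform (59-bin) mapping is supported")
        if self.cell_size < 3:
            raise LBPConfigError(f"cell_size must be >= 3, got {self.cell_size}")
        if self.interpolation not in ("bilinear", "nearest"):
            raise LBPConfigError(f"unknown interpolation '{self.interpolation}'")


def transitions(code: int) -> int:
    """Number of circular 0<->1 transitions in the 8-bit string of *code*."""
    if not 0 <= code <= 255:
        raise ValueError(f"code must be in [0, 255], got {code}")
    bits = [(code >> k) & 1 for k in range(8)]
    return sum(bits[k] != bits[(k + 1) % 8] for k in range(8))


def _build_uniform_lut() -> np.ndarray:
    """Map each 8-bit code to its histogram bin (uniform ascending, catch-all last)."""
    uniform_codes = [c for c in range(256) if transitions(c) <= 2]
    lut = np.full(256, N_UNIFORM_BINS - 1, dtype=np.intp)
    for bin_idx, code in enumerate(sorted(uniform_codes)):
        lut[code] = bin_idx
    return lut


UNIFORM_LUT = _build_uniform_lut()


def uniform_bin_index(code: int) -> int:
    """Histogram bin for *code*: uniform codes -> 0..57, others -> 58."""
    if not 0 <= code <= 255:
        raise ValueError(f"code must be in [0, 255], got {code}")
    return int(UNIFORM_LUT[code])


def lbp_code(center: float, neighbors) -> int:
    """8-bit code from a center intensity and its 8 ordered neighbor samples.

    Bit k is set iff neighbors[k] >= center (ties count as 1); bit k
    carries weight 2^k. Neighbor 0 is east, order counterclockwise.
    """
    neighbors = np.asarray(neighbors, dtype=np.float64)
    if neighbors.shape != (8,):
        raise ValueError(f"expected 8 neighbor samples, got shape {neighbors.shape}")
    bits = neighbors >= center
    return int(np.sum(bits * (1 << np.arange(8))))

# neighbor k at angle 45k° from east, counterclockwise (image rows grow
# downward, so CCW means row offset -sin). (row_offset, col_offset):
_S = np.sqrt(2.0) / 2.0
NEIGHBOR_OFFSETS = [
    (0.0, 1.0), (-_S, _S), (-1.0, 0.0), (-_S, -_S),
    (0.0, -1.0), (_S, -_S), (1.0, 0.0), (_S, _S),
]
_NEAREST_OFFSETS = [
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
]


def _bilinear_shift(f: np.ndarray, dr: float, dc: float) -> np.ndarray:
    """Sample f at (r + dr, c + dc) for all interior pixels (bilinear)."""
    r0, c0 = int(np.floor(dr)), int(np.floor(dc))
    fr, fc = dr - r0, dc - c0
    # interior pixel (r, c), r, c in [1, n-2]; corners r+r0 .. r+r0+1 stay in range
    def win(ro, co):
        return f[1 + ro : f.shape[0] - 1 + ro, 1 + co : f.shape[1] - 1 + co]

    if fr == 0.0 and fc == 0.0:
        return win(r0, c0)
    return (
        win(r0, c0) * (1 - fr) * (1 - fc)
        + win(r0, c0 + 1) * (1 - fr) * fc
        + win(r0 + 1, c0) * fr * (1 - fc)
        + win(r0 + 1, c0 + 1) * fr * fc
    )


def lbp_code_map(img: np.ndarray, interpolation: str = "bilinear") -> np.ndarray:
    """Per-pixel LBP codes for all interior pixels.

    Returns an (h-2, w-2) int array; the 1-pixel border produces no code.
    """
    img = check_gray_image(img)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise LBPConfigError(f"image {img.shape} too small for radius-1 LBP")
    f = img.astype(np.float64)
    center = f[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.intp)
    if interpolation == "bilinear":
        offsets = NEIGHBOR_OFFSETS
        for k, (dr, dc) in enumerate(offsets):
            codes += (_bilinear_shift(f, dr, dc) >= center).astype(np.intp) << k
    else:
        for k, (dr, dc) in enumerate(_NEAREST_OFFSETS):
            sample = f[1 + dr : f.shape[0] - 1 + dr, 1 + dc : f.shape[1] - 1 + dc]
            codes += (sample >= center).astype(np.intp) << k
    return codes


def lbp_dim(cfg: LBPConfig, image_size: tuple[int, int]) -> int:
    """Descriptor length: (h/cell) * (w/cell) * 59."""
    h, w = image_size
    if h % cfg.cell_size or w % cfg.cell_size:
        raise LBPConfigError(
            f"image size {h}x{w} not divisible by cell_size {cfg.cell_size}"
        )
    return (h // cfg.cell_size) * (w // cfg.cell_size) * N_UNIFORM_BINS


def extract_lbp(img: np.ndarray, cfg: LBPConfig | None = None) -> np.ndarray:
    """Concatenated per-cell L2-normalized uniform-LBP histograms."""
    cfg = cfg or LBPConfig()
    img = check_gray_image(img)
    h, w = img.shape
    if h % cfg.cell_size or w % cfg.cell_size:
        raise LBPConfigError(
            f"image size {h}x{w} not divisible by cell_size {cfg.cell_size}"
        )
    cy, cx = h // cfg.cell_size, w // cfg.cell_size
    codes = lbp_code_map(img, cfg.interpolation)
    bins = UNIFORM_LUT[codes]
    # coded pixel (i, j) of the map sits at image coordinate (i+1, j+1)
    rows, cols = np.indices(bins.shape)
    cell_r = (rows + 1) // cfg.cell_size
    cell_c = (cols + 1) // cfg.cell_size
    hist = np.zeros((cy, cx, N_UNIFORM_BINS))
    np.add.at(hist, (cell_r, cell_c, bins), 1.0)
    flat = hist.reshape(cy * cx, N_UNIFORM_BINS)
    norms = np.linalg.norm(flat, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0  # zero-vector guard (unreachable for cell_size >= 3)
    return (flat / norms).reshape(-1)


def combine_features(hog_vec: np.ndarray, lbp_vec: np.ndarray | None) -> np.ndarray:
    """Concatenate descriptors, HOG first; ``None``/empty LBP is identity."""
    if lbp_vec is None or np.size(lbp_vec) == 0:
        return np.asarray(hog_vec, dtype=np.float64)
    return np.concatenate([np.asarray(hog_vec, np.float64), np.asarray(lbp_vec, np.float64)])


class LBPDescriptor(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: stack of images -> uniform-LBP matrix."""

    def __init__(self, cell_size: int = 64, interpolation: str = "bilinear"):
        self.cell_size = cell_size
        self.interpolation = interpolation

    def _config(self) -> LBPConfig:
        return LBPConfig(cell_size=self.cell_size, interpolation=self.interpolation)

    def fit(self, X, y=None):
        images = _as_stack(X)
        self.image_size_ = tuple(images[0].shape)
        self.n_features_out_ = lbp_dim(self._config(), self.image_size_)
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._config()
        return np.vstack([extract_lbp(img, cfg) for img in _as_stack(X)])

    def fingerprint(self) -> dict:
        return {
            "descriptor": "lbp",
            "cell_size": self.cell_size,
            "radius": 1,
            "n_neighbors": 8,
            "interpolation": self.interpolation,
        }


def _as_stack(X) -> list[np.ndarray]:
    if isinstance(X, np.ndarray) and X.ndim == 3:
        return [X[i] for i in range(X.shape[0])]
    images = list(X)
    if not images:
        raise LBPConfigError("empty image collection")
    return images
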