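import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphsvm.lbp import (
    LBPConfig,
    LBPConfigError,
    LBPDescriptor,
    N_UNIFORM_BINS,
    NEIGHBOR_OFFSETS,
    UNIFORM_LUT,
    combine_features,
    extract_lbp,
    lbp_code,
    lbp_code_map,
    lbp_dim,
    transitions,
    uniform_bin_index,
)


class TestLBPCode:
    def test_all_equal_neighbors_tie_to_ones(self):
        assert lbp_code(100, [100] * 8) == 255

    def test_all_below_center(self):
        assert lbp_code(100, [99] * 8) == 0

    def test_matches_bit_by_bit_oracle(self, rng):
        for _ in range(1000):
            center = rng.integers(0, 256)
            neigh = rng.integers(0, 256, 8)
            expected = sum((1 << k) for k in range(8) if neigh[k] >= center)
            assert lbp_code(center, neigh) == expected

    def test_monotone_transform_invariance(self, rng):
        # strictly monotone intensity maps leave the code unchanged
        center = 90
        neigh = rng.integers(0, 256, 8)
        f = lambda x: np.asarray(x, dtype=np.float64) * 1.7 + 4.0
        assert lbp_code(center, neigh) == lbp_code(f(center), f(neigh))


class TestTransitions:
    @pytest.mark.parametrize("code, expected", [
        (0, 0),
        (255, 0),
        (0b00001111, 2),
        (0b01010101, 8),
    ])
    def test_known_codes(self, code, expected):
        assert transitions(code) == expected

    @given(code=st.integers(0, 255))
    @settings(derandomize=True, max_examples=64)
    def test_matches_circular_scan(self, code):
        bits = f"{code:08b}"
        circ = bits + bits[0]
        assert transitions(code) == sum(a != b for a, b in zip(circ, circ[1:]))


class TestUniformBins:
    def test_exactly_58_uniform_codes(self):
        uniform = [c for c in range(256) if transitions(c) <= 2]
        assert len(uniform) == 58
        assert N_UNIFORM_BINS == 59

    def test_injective_on_uniform_codes(self):
        uniform = [c for c in range(256) if transitions(c) <= 2]
        bins = {uniform_bin_index(c) for c in uniform}
        assert bins == set(range(58))

    def test_nonuniform_share_catch_all(self):
        for code in range(256):
            if transitions(code) > 2:
                assert uniform_bin_index(code) == 58
        assert uniform_bin_index(0b01010101) == 58


class TestCodeMap:
    def test_matches_per_pixel_sampling_oracle(self, rng):
        img = rng.integers(0, 256, (10, 10)).astype(np.uint8)
        codes = lbp_code_map(img, "bilinear")
        f = img.astype(float)

        def bilinear(r, c):
            r0, c0 = int(np.floor(r)), int(np.floor(c))
            fr, fc = r - r0, c - c0
            if fr == 0 and fc == 0:  # axial neighbor: exact grid point
                return f[r0, c0]
            return (f[r0, c0] * (1 - fr) * (1 - fc) + f[r0, c0 + 1] * (1 - fr) * fc
                    + f[r0 + 1, c0] * fr * (1 - fc) + f[r0 + 1, c0 + 1] * fr * fc)

        for r in range(1, 9):
            for c in range(1, 9):
                samples = [bilinear(r + dr, c + dc) for dr, dc in NEIGHBOR_OFFSETS]
                assert codes[r - 1, c - 1] == lbp_code(f[r, c], samples)

    def test_matches_reference_implementation(self, rng):
        skimage = pytest.importorskip("skimage.feature")
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        ref = skimage.local_binary_pattern(img.astype(np.float64), 8, 1,
                                           method="default")
        assert np.array_equal(lbp_code_map(img, "bilinear"),
                              ref[1:-1, 1:-1].astype(int))

    def test_nearest_variant_matches_integer_oracle(self, rng):
        img = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        codes = lbp_code_map(img, "nearest")
        offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1),
                   (0, -1), (1, -1), (1, 0), (1, 1)]
        for r in range(1, 7):
            for c in range(1, 7):
                samples = [img[r + dr, c + dc] for dr, dc in offsets]
                assert codes[r - 1, c - 1] == lbp_code(img[r, c], samples)


class TestExtractLBP:
    def test_dimension_contract(self):
        img = np.zeros((512, 512), dtype=np.uint8)
        assert extract_lbp(img, LBPConfig(cell_size=64)).shape == (3776,)

    @pytest.mark.parametrize("cell, size, expected", [
        (64, (512, 512), 3776),
        (64, (64, 64), 59),
        (32, (512, 512), 15104),
    ])
    def test_lbp_dim(self, cell, size, expected):
        assert lbp_dim(LBPConfig(cell_size=cell), size) == expected

    def test_constant_image_unit_basis_per_cell(self):
        # constant image: every code is 255 (all ties), a uniform pattern
        img = np.full((64, 64), 80, dtype=np.uint8)
        v = extract_lbp(img, LBPConfig(cell_size=32)).reshape(4, 59)
        expected_bin = uniform_bin_index(255)
        for hist in v:
            assert hist[expected_bin] == pytest.approx(1.0)
            assert np.linalg.norm(hist) == pytest.approx(1.0)

    def test_histogram_counts_conserved(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        cfg = LBPConfig(cell_size=32)
        codes = lbp_code_map(img)
        bins = UNIFORM_LUT[codes]
        # re-tally raw counts per cell and compare against the normalized output
        raw = np.zeros((2, 2, 59))
        for i in range(codes.shape[0]):
            for j in range(codes.shape[1]):
                raw[(i + 1) // 32, (j + 1) // 32, bins[i, j]] += 1
        assert raw.sum() == codes.size
        v = extract_lbp(img, cfg).reshape(4, 59)
        flat = raw.reshape(4, 59)
        assert np.allclose(v, flat / np.linalg.norm(flat, axis=1, keepdims=True))

    def test_normalized_cells_unit_norm(self, rng):
        img = rng.integers(0, 256, (96, 96)).astype(np.uint8)
        v = extract_lbp(img, LBPConfig(cell_size=32)).reshape(-1, 59)
        assert np.allclose(np.linalg.norm(v, axis=1), 1.0)

    def test_divisibility_enforced(self):
        with pytest.raises(LBPConfigError, match="divisible"):
            extract_lbp(np.zeros((100, 96), np.uint8), LBPConfig(cell_size=32))

    def test_unsupported_variants_rejected(self):
        with pytest.raises(LBPConfigError):
            LBPConfig(rotation_invariant=True)
        with pytest.raises(LBPConfigError):
            LBPConfig(n_neighbors=16)


class TestCombineFeatures:
    def test_concatenation_order_and_length(self, rng):
        hog = rng.random(8100)
        lbp = rng.random(3776)
        v = combine_features(hog, lbp)
        assert v.shape == (11876,)
        assert np.array_equal(v[:8100], hog)
        assert np.array_equal(v[8100:], lbp)

    def test_hog_only_mode(self, rng):
        hog = rng.random(10)
        assert np.array_equal(combine_features(hog, None), hog)
        assert np.array_equal(combine_features(hog, np.array([])), hog)


class TestLBPDescriptorEstimator:
    def test_sklearn_interface(self, rng):
        X = rng.integers(0, 256, (3, 64, 64)).astype(np.uint8)
        desc = LBPDescriptor(cell_size=32)
        out = desc.fit(X).transform(X)
        assert out.shape == (3, desc.n_features_out_) == (3, 4 * 59)
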