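"""NDVI, GLCM and Sobel against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hsiseg.features import (
    DEFAULT_OFFSETS,
    SOBEL_X,
    SOBEL_Y,
    build_artificial_stack,
    compute_ndvi,
    glcm_map,
    glcm_window_features,
    quantize_gray,
    sobel_edges,
)
from hsiseg.preprocess import fit_pca
from hsiseg.synthetic import SceneSpec, generate_scene
from hsiseg.types import SpectralCube


def cube_from_bands(nir, red, nir_nm=800.0, red_nm=670.0):
    data = np.stack([np.asarray(red, dtype=float),
                     np.asarray(nir, dtype=float)], axis=-1)
    return SpectralCube(data, wavelengths=[red_nm, nir_nm])


class TestNDVI:
    def test_direct_arithmetic(self):
        cube = cube_from_bands(nir=np.full((2, 2), 0.8),
                               red=np.full((2, 2), 0.2))
        np.testing.assert_allclose(compute_ndvi(cube), 0.6)

    def test_equal_bands_give_zero(self):
        cube = cube_from_bands(nir=np.full((2, 2), 0.5),
                               red=np.full((2, 2), 0.5))
        np.testing.assert_allclose(compute_ndvi(cube), 0.0)

    def test_zero_denominator_convention(self):
        cube = cube_from_bands(nir=np.zeros((2, 2)), red=np.zeros((2, 2)))
        np.testing.assert_array_equal(compute_ndvi(cube), 0.0)

    @given(hnp.arrays(np.float64, (3, 3, 2),
                      elements=st.floats(0, 10, allow_nan=False)))
    def test_bounded_on_nonnegative_cubes(self, data):
        cube = SpectralCube(data, wavelengths=[670.0, 800.0])
        ndvi = compute_ndvi(cube)
        assert np.all(ndvi >= -1) and np.all(ndvi <= 1)

    def test_invariant_to_uniform_scaling(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0.01, 1, size=(8, 8, 2))
        a = compute_ndvi(SpectralCube(data, wavelengths=[670.0, 800.0]))
        b = compute_ndvi(SpectralCube(2.5 * data,
                                      wavelengths=[670.0, 800.0]))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_signs_match_land_cover_on_clean_scene(self):
        spec = SceneSpec(height=32, width=32, n_bands=16, n_classes=2,
                         class_kinds=("vegetation", "water"),
                         noise_sigma=0.0, texture_amplitude=0.0,
                         illumination_amplitude=0.0, seed=2)
        cube, labels, _ = generate_scene(spec)
        ndvi = compute_ndvi(cube)
        assert np.all(ndvi[labels.labels == 1] > 0)
        assert np.all(ndvi[labels.labels == 2] < 0)

    def test_missing_wavelengths_error_directs_user(self):
        cube = SpectralCube(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="band indices"):
            compute_ndvi(cube)


class TestQuantize:
    def test_constant_image_is_bin_zero(self):
        np.testing.assert_array_equal(
            quantize_gray(np.full((4, 4), 0.3)), 0)

    def test_linear_ramp_quartile_bins(self):
        ramp = np.linspace(0, 1, 8).reshape(1, 8)
        q = quantize_gray(ramp, levels=4)
        np.testing.assert_array_equal(q, [[0, 0, 1, 1, 2, 2, 3, 3]])

    def test_output_strictly_below_levels(self):
        rng = np.random.default_rng(3)
        q = quantize_gray(rng.normal(size=(16, 16)), levels=16)
        assert q.min() >= 0 and q.max() < 16


def glcm_oracle(window, levels, offsets):
    """Brute-force pair enumeration, independent of the implementation."""
    counts = {}
    h, w = window.shape
    n = 0
    for dr, dc in offsets:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    i, j = int(window[r, c]), int(window[r2, c2])
                    counts[(i, j)] = counts.get((i, j), 0) + 1
                    counts[(j, i)] = counts.get((j, i), 0) + 1
                    n += 2
    hom = sum(v / n / (1 + (i - j) ** 2) for (i, j), v in counts.items())
    dis = sum(v / n * abs(i - j) for (i, j), v in counts.items())
    mean = sum(v / n * i for (i, j), v in counts.items())
    ent = -sum((v / n) * np.log(v / n) for v in counts.values())
    return hom, mean, dis, ent


class TestGLCMWindow:
    def test_constant_window_limits(self):
        hom, mean, dis, ent = glcm_window_features(
            np.full((3, 3), 5, dtype=int))
        assert hom == pytest.approx(1.0)
        assert dis == pytest.approx(0.0)
        assert ent == pytest.approx(0.0)
        assert mean == pytest.approx(5.0)

    def test_checkerboard_hand_enumeration(self):
        board = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        # offset (0,1): 6 horizontal pairs, all (0,1) or (1,0)
        hom, mean, dis, ent = glcm_window_features(
            board, levels=2, offsets=((0, 1),))
        assert hom == pytest.approx(0.5)  # all pairs differ by 1
        assert dis == pytest.approx(1.0)
        assert mean == pytest.approx(0.5)
        assert ent == pytest.approx(np.log(2))  # two cells at P = 1/2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        window = rng.integers(0, 8, size=(5, 5))
        ours = glcm_window_features(window, levels=8)
        oracle = glcm_oracle(window, 8, DEFAULT_OFFSETS)
        np.testing.assert_allclose(ours, oracle, atol=1e-12)

    def test_matches_skimage_cross_check(self):
        feature = pytest.importorskip("skimage.feature")
        rng = np.random.default_rng(4)
        window = rng.integers(0, 8, size=(7, 7))
        hom, _, dis, _ = glcm_window_features(window, levels=8,
                                              offsets=((0, 1),))
        m = feature.graycomatrix(window.astype(np.uint8), [1], [0],
                                 levels=8, symmetric=True, normed=True)
        assert hom == pytest.approx(
            float(feature.graycoprops(m, "homogeneity")[0, 0]), abs=1e-12)
        assert dis == pytest.approx(
            float(feature.graycoprops(m, "dissimilarity")[0, 0]), abs=1e-12)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            glcm_window_features(np.zeros((1, 1), dtype=int))


class TestGLCMMap:
    def test_constant_image_maps(self):
        out = glcm_map(np.zeros((8, 8), dtype=np.int32))
        np.testing.assert_allclose(out[:, :, 0], 1.0)  # homogeneity
        np.testing.assert_allclose(out[:, :, 2], 0.0)  # dissimilarity
        np.testing.assert_allclose(out[:, :, 3], 0.0)  # entropy

    def test_every_pixel_matches_windowed_call(self):
        rng = np.random.default_rng(6)
        img = rng.integers(0, 16, size=(16, 16)).astype(np.int32)
        out = glcm_map(img, window=3, levels=16)
        padded = np.pad(img, 1, mode="reflect")
        for r in range(16):
            for c in range(16):
                win = padded[r:r + 3, c:c + 3]
                hom, mean, dis, ent = glcm_window_features(win, levels=16)
                np.testing.assert_allclose(
                    out[r, c], [hom, mean, dis, ent], atol=1e-12)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 16, size=(12, 12)).astype(np.int32)
        np.testing.assert_array_equal(glcm_map(img), glcm_map(img))

    def test_float_input_rejected(self):
        with pytest.raises(ValueError, match="quantize"):
            glcm_map(np.zeros((4, 4)))


class TestSobel:
    def test_constant_image_zero(self):
        np.testing.assert_allclose(sobel_edges(np.full((6, 6), 3.0)), 0.0)

    def test_column_ramp_interior_gradient(self):
        img = np.tile(np.arange(8, dtype=float), (8, 1))
        from scipy.ndimage import correlate

        gx = correlate(img, SOBEL_X, mode="reflect")
        gy = correlate(img, SOBEL_Y, mode="reflect")
        assert np.all(gx[1:-1, 1:-1] == 8.0)  # 2 * (1 + 2 + 1)
        assert np.all(gy[1:-1, 1:-1] == 0.0)
        np.testing.assert_allclose(
            sobel_edges(img)[1:-1, 1:-1], 8.0, atol=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=(10, 10))
        padded = np.pad(img, 1, mode="reflect")
        gx = np.zeros_like(img)
        gy = np.zeros_like(img)
        for r in range(10):
            for c in range(10):
                win = padded[r:r + 3, c:c + 3]
                gx[r, c] = (win * SOBEL_X).sum()
                gy[r, c] = (win * SOBEL_Y).sum()
        np.testing.assert_allclose(sobel_edges(img), np.hypot(gx, gy),
                                   atol=1e-12)

    def test_rotation_swaps_gradient_axes(self):
        rng = np.random.default_rng(7)
        img = rng.normal(size=(9, 9))
        mag = sobel_edges(img)
        mag_rot = sobel_edges(np.rot90(img))
        np.testing.assert_allclose(np.rot90(mag), mag_rot, atol=1e-10)


class TestArtificialStack:
    @pytest.fixture(scope="class")
    def stack(self, small_scene):
        _, cube, labels, members = small_scene
        model = fit_pca(cube, k=6)
        return build_artificial_stack(cube, model), cube, labels, members

    def test_shape_and_finiteness(self, stack):
        fs, cube, _, _ = stack
        assert fs.data.shape == (*cube.shape, 6)
        assert np.isfinite(fs.data).all()

    def test_channels_normalized_with_invertible_record(self, stack):
        fs, cube, _, _ = stack
        assert fs.data.min() >= 0 and fs.data.max() <= 1
        ndvi_raw = fs.raw_channel("ndvi")
        np.testing.assert_allclose(ndvi_raw, compute_ndvi(cube), atol=1e-5)

    def test_ndvi_sign_separates_vegetation_from_water(self):
        spec = SceneSpec(height=64, width=64, n_bands=16, n_classes=3,
                         class_kinds=("vegetation", "water", "vegetation"),
                         noise_sigma=0.0, texture_amplitude=0.0,
                         illumination_amplitude=0.0, seed=5)
        cube, labels, _ = generate_scene(spec)
        model = fit_pca(cube, k=6)
        fs = build_artificial_stack(cube, model)
        ndvi = fs.raw_channel("ndvi")
        for cid, kind in enumerate(spec.class_kinds, start=1):
            mean = ndvi[labels.labels == cid].mean()
            assert mean > 0 if kind == "vegetation" else mean < 0
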