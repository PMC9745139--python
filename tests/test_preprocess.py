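"""Standardized PCA against independent oracles; tiling and splitting."""

import numpy as np
import pytest

from hsiseg.preprocess import (
    apply_pca,
    fit_pca,
    load_tiles,
    mosaic_labels,
    save_tiles,
    split_tiles,
    tile_scene,
)
from hsiseg.types import ClassScheme, FeatureStack, LabelMap, SpectralCube


def random_cube(h=50, w=50, b=8, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(h, w, 3)) @ rng.normal(size=(3, b))
    data = base + 0.1 * rng.normal(size=(h, w, b))
    return SpectralCube(data.astype(np.float32))


class TestFitPCA:
    def test_matches_covariance_eigendecomposition_oracle(self):
        cube = random_cube()
        model = fit_pca(cube, k=6)
        # independent oracle: brute-force correlation-matrix eigensolve
        x = cube.data.reshape(-1, 8).astype(np.float64)
        z = (x - x.mean(0)) / x.std(0)
        eigval, eigvec = np.linalg.eigh(np.cov(z, rowvar=False))
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        np.testing.assert_allclose(model.explained_variance, eigval[:6],
                                   atol=1e-8)
        for j in range(6):
            dot = abs(np.dot(model.components[:, j], eigvec[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_matches_sklearn_on_standardized_data(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        cube = random_cube(seed=3)
        model = fit_pca(cube, k=4)
        x = cube.data.reshape(-1, 8).astype(np.float64)
        z = (x - x.mean(0)) / x.std(0)
        sk = sklearn.PCA(n_components=4).fit(z)
        np.testing.assert_allclose(
            np.abs(model.components.T), np.abs(sk.components_), atol=1e-6)
        np.testing.assert_allclose(model.explained_variance_ratio,
                                   sk.explained_variance_ratio_, atol=1e-8)

    def test_rank_one_data_concentrates_variance(self):
        rng = np.random.default_rng(1)
        band1 = rng.normal(size=(20, 20))
        cube = SpectralCube(np.stack([band1, 2 * band1], axis=-1))
        model = fit_pca(cube, k=2)
        np.testing.assert_allclose(model.explained_variance_ratio,
                                   [1.0, 0.0], atol=1e-10)

    def test_full_rank_round_trip(self):
        cube = random_cube(seed=5)
        model = fit_pca(cube, k=8)
        x = cube.data.reshape(-1, 8).astype(np.float64)
        z = (x - model.mean) / model.scale
        back = (z @ model.components) @ model.components.T
        np.testing.assert_allclose(back, z, atol=1e-6)

    def test_variance_ratio_non_increasing_and_bounded(self):
        model = fit_pca(random_cube(seed=9), k=6)
        evr = model.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert np.all(evr >= 0) and evr.sum() <= 1 + 1e-12

    def test_components_orthonormal(self):
        model = fit_pca(random_cube(seed=2), k=6)
        gram = model.components.T @ model.components
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)

    def test_sign_convention_deterministic(self):
        model = fit_pca(random_cube(seed=4), k=6)
        peaks = model.components[
            np.abs(model.components).argmax(axis=0), np.arange(6)]
        assert np.all(peaks > 0)

    def test_constant_band_warns_not_crashes(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(10, 10, 4))
        data[:, :, 2] = 0.7
        with pytest.warns(UserWarning, match="constant band"):
            model = fit_pca(SpectralCube(data), k=2)
        assert model.scale[2] == 1.0

    def test_k_larger_than_bands_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            fit_pca(random_cube(), k=9)


class TestApplyPCA:
    def test_scores_centered_and_variance_matches_eigenvalues(self):
        cube = random_cube(seed=6)
        model = fit_pca(cube, k=6)
        scores = apply_pca(cube, model).data.reshape(-1, 6).astype(np.float64)
        np.testing.assert_allclose(scores.mean(0), 0, atol=1e-5)
        total = scores.var(0, ddof=1).sum()
        np.testing.assert_allclose(total, model.explained_variance.sum(),
                                   rtol=1e-5)

    def test_matches_explicit_matmul_oracle(self):
        cube = random_cube(seed=8)
        model = fit_pca(cube, k=5)
        scores = apply_pca(cube, model)
        x = cube.data.reshape(-1, 8).astype(np.float64)
        expected = ((x - model.mean) / model.scale) @ model.components
        np.testing.assert_allclose(
            scores.data.reshape(-1, 5), expected, atol=1e-4)

    def test_band_count_mismatch_rejected(self):
        model = fit_pca(random_cube(), k=3)
        other = SpectralCube(np.zeros((5, 5, 7)))
        with pytest.raises(ValueError, match="bands"):
            apply_pca(other, model)


def make_scene(h, w, c=3, seed=0):
    rng = np.random.default_rng(seed)
    pca = SpectralCube(rng.normal(size=(h, w, 6)).astype(np.float32))
    stack = FeatureStack(rng.uniform(size=(h, w, 6)).astype(np.float32))
    labels = LabelMap(
        rng.integers(1, c + 1, size=(h, w)).astype(np.int32),
        ClassScheme.generic(c),
    )
    return pca, stack, labels


class TestTiling:
    def test_exact_grid_counts(self):
        pca, stack, labels = make_scene(256, 256)
        tiles = tile_scene(pca, stack, labels, tile=64)
        assert len(tiles) == 16
        assert all(t.pca.shape == (64, 64, 6) for t in tiles)
        assert all(t.valid == (64, 64) for t in tiles)

    def test_remainder_padding(self):
        pca, stack, labels = make_scene(300, 300)
        tiles = tile_scene(pca, stack, labels, tile=64)
        assert len(tiles) == 25  # ceil(300/64) = 5 per axis
        edge = [t for t in tiles if t.origin == (256, 256)][0]
        assert edge.valid == (44, 44)
        assert edge.pca.shape == (64, 64, 6)

    def test_origins_partition_scene(self):
        pca, stack, labels = make_scene(300, 200)
        tiles = tile_scene(pca, stack, labels, tile=64)
        covered = np.zeros((300, 200), dtype=int)
        for t in tiles:
            r0, c0 = t.origin
            vh, vw = t.valid
            covered[r0:r0 + vh, c0:c0 + vw] += 1
        assert np.all(covered == 1)

    def test_mosaic_inverts_tiling(self):
        pca, stack, labels = make_scene(300, 200)
        tiles = tile_scene(pca, stack, labels, tile=64)
        back = mosaic_labels(list(tiles), [t.labels for t in tiles],
                             (300, 200))
        np.testing.assert_array_equal(back, labels.labels)

    def test_small_scene_single_padded_tile(self):
        pca, stack, labels = make_scene(40, 40)
        with pytest.warns(UserWarning, match="smaller"):
            tiles = tile_scene(pca, stack, labels, tile=64)
        assert len(tiles) == 1
        assert tiles[0].valid == (40, 40)

    def test_tile_size_must_be_divisible_by_16(self):
        pca, stack, labels = make_scene(64, 64)
        with pytest.raises(ValueError, match="16"):
            tile_scene(pca, stack, labels, tile=50)


class TestSplit:
    @pytest.fixture
    def tiles(self):
        pca, stack, labels = make_scene(256, 256)
        return tile_scene(pca, stack, labels, tile=64)

    def test_eight_to_two_counts(self, tiles):
        train, test = split_tiles(tiles, ratio=0.8, seed=0)
        assert len(train) == 13  # ceil(0.8 * 16)
        assert len(test) == 3

    def test_split_is_disjoint_and_exhaustive(self, tiles):
        train, test = split_tiles(tiles, ratio=0.8, seed=1)
        origins = {t.origin for t in train} | {t.origin for t in test}
        assert len(origins) == 16
        assert not ({t.origin for t in train} & {t.origin for t in test})

    def test_seeded_determinism(self, tiles):
        a_train, _ = split_tiles(tiles, seed=5)
        b_train, _ = split_tiles(tiles, seed=5)
        assert [t.origin for t in a_train] == [t.origin for t in b_train]

    def test_too_few_tiles_rejected(self, tiles):
        from hsiseg.preprocess import TileSet

        with pytest.raises(ValueError, match="2 tiles"):
            split_tiles(TileSet([tiles[0]]), seed=0)


def test_tileset_save_load_round_trip(tmp_path):
    pca, stack, labels = make_scene(128, 128)
    tiles = tile_scene(pca, stack, labels, tile=64)
    path = tmp_path / "tiles.npz"
    save_tiles(tiles, path)
    back = load_tiles(path)
    assert len(back) == len(tiles)
    for a, b in zip(tiles, back):
        np.testing.assert_array_equal(a.pca, b.pca)
        np.testing.assert_array_equal(a.artificial, b.artificial)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.origin == b.origin and a.valid == b.valid
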