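"""Band reduction, tiling and train/test splitting.

PCA here is the standardized (correlation-matrix) variant: every band is
z-scored before the covariance eigendecomposition, so bands with large
radiometric ranges do not dominate the components. The hyperspectral cube
is flattened to a samples-by-bands matrix, reduced to ``k`` scores per
pixel (6 by default), and reshaped back into an image whose "bands" are
component scores.

Scenes are then cut into a non-overlapping grid of square tiles (edge
divisible by 16, so four 2x downsamplings stay integral), remainders
padded by reflection with the padding recorded, and split 8:2 at the tile
level by a seeded shuffle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .types import FeatureStack, LabelMap, SpectralCube

__all__ = [
    "PCAModel",
    "fit_pca",
    "apply_pca",
    "Tile",
    "TileSet",
    "tile_scene",
    "split_tiles",
    "save_tiles",
    "load_tiles",
    "mosaic_labels",
]


@dataclass
class PCAModel:
    """Standardized PCA fitted to a cube's pixel spectra.

    ``components`` is ``B x k`` with orthonormal columns; scores are
    ``(x - mean) / scale @ components``. Component signs are fixed so each
    column's largest-magnitude loading is positive, making fits
    deterministic across eigensolvers.
    """

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_bands(self) -> int:
        return self.components.shape[0]

    @property
    def k(self) -> int:
        return self.components.shape[1]

    def save(self, path) -> None:
        np.savez(
            path,
            mean=self.mean,
            scale=self.scale,
            components=self.components,
            explained_variance=self.explained_variance,
            explained_variance_ratio=self.explained_variance_ratio,
        )

    @classmethod
    def load(cls, path) -> "PCAModel":
        with np.load(path) as npz:
            return cls(**{k: npz[k] for k in npz.files})


def fit_pca(cube: SpectralCube, k: int = 6) -> PCAModel:
    """Fit standardized PCA to the cube's pixels and keep the top ``k``
    components by eigenvalue.

    Constant (zero-variance) bands get unit scale with a warning instead
    of dividing by zero; they simply contribute nothing to the components.
    """
    b = cube.n_bands
    if k > b:
        raise ValueError(f"k={k} exceeds the {b} available bands")
    x = cube.data.reshape(-1, b).astype(np.float64)
    if x.shape[0] < k + 1:
        raise ValueError("need at least k+1 pixels to fit PCA")
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    zero = scale <= 1e-10 * np.maximum(1.0, np.abs(mean))
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} constant band(s); their scale is set to 1",
            stacklevel=2,
        )
        scale = np.where(zero, 1.0, scale)
    z = (x - mean) / scale
    cov = z.T @ z / (x.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    components = eigvec[:, :k]
    # deterministic sign: largest-|loading| entry of each column positive
    flip = components[np.abs(components).argmax(axis=0),
                      np.arange(k)] < 0
    components = components * np.where(flip, -1.0, 1.0)
    total = eigval.sum()
    ratio = eigval[:k] / total if total > 0 else np.zeros(k)
    return PCAModel(
        mean=mean,
        scale=scale,
        components=components,
        explained_variance=eigval[:k],
        explained_variance_ratio=ratio,
    )


def apply_pca(cube: SpectralCube, model: PCAModel) -> SpectralCube:
    """Project a cube onto the fitted components.

    The result is a ``H x W x k`` cube of component scores; wavelengths no
    longer apply and are dropped.
    """
    if cube.n_bands != model.n_bands:
        raise ValueError(
            f"cube has {cube.n_bands} bands but the PCA model was fitted "
            f"on {model.n_bands}"
        )
    z = (cube.data.reshape(-1, model.n_bands) - model.mean) / model.scale
    scores = z @ model.components
    return SpectralCube(
        scores.reshape(*cube.shape, model.k).astype(np.float32)
    )


# ---------------------------------------------------------------------------
# Tiling

@dataclass
class Tile:
    """One tile of the scene: the two network inputs plus labels.

    ``origin`` is the (row, col) of the tile's top-left corner in the
    scene; ``valid`` is its unpadded extent (equal to the tile size except
    at the right/bottom edges, where reflection padding filled the rest).
    """

    pca: np.ndarray
    artificial: np.ndarray | None
    labels: np.ndarray
    origin: tuple[int, int]
    valid: tuple[int, int]

    @property
    def size(self) -> int:
        return self.pca.shape[0]

    def valid_mask(self) -> np.ndarray:
        m = np.zeros(self.labels.shape, dtype=bool)
        m[: self.valid[0], : self.valid[1]] = True
        return m


@dataclass
class TileSet:
    tiles: list[Tile]
    role: str = "all"  # train | test | all
    scene_shape: tuple[int, int] | None = None

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)

    def __getitem__(self, i: int) -> Tile:
        return self.tiles[i]


def _reflect_pad_to(arr: np.ndarray, h: int, w: int) -> np.ndarray:
    pads = [(0, h - arr.shape[0]), (0, w - arr.shape[1])]
    pads += [(0, 0)] * (arr.ndim - 2)
    return np.pad(arr, pads, mode="reflect")


def tile_scene(
    pca_cube: SpectralCube,
    feature_stack: FeatureStack | None,
    labels: LabelMap,
    tile: int = 64,
) -> TileSet:
    """Cut the scene into a non-overlapping grid of ``tile``-pixel squares.

    Right/bottom remainders are padded by reflection up to the full tile
    size and the padding recorded per tile so losses and metrics can mask
    it out. A scene smaller than one tile yields a single padded tile with
    a warning.
    """
    if tile % 16 != 0:
        raise ValueError("tile size must be divisible by 16")
    h, w = pca_cube.shape
    if labels.shape != (h, w):
        raise ValueError("labels do not match the scene")
    if feature_stack is not None and feature_stack.shape != (h, w):
        raise ValueError("feature stack does not match the scene")
    if h < tile or w < tile:
        warnings.warn(
            f"scene {h}x{w} is smaller than one {tile}-pixel tile; "
            "emitting a single padded tile", stacklevel=2,
        )
    ny, nx = math.ceil(h / tile), math.ceil(w / tile)
    tiles: list[Tile] = []
    for iy in range(ny):
        for ix in range(nx):
            r0, c0 = iy * tile, ix * tile
            r1, c1 = min(r0 + tile, h), min(c0 + tile, w)
            pca = _reflect_pad_to(pca_cube.data[r0:r1, c0:c1], tile, tile)
            art = None
            if feature_stack is not None:
                art = _reflect_pad_to(
                    feature_stack.data[r0:r1, c0:c1], tile, tile
                )
            lab = _reflect_pad_to(labels.labels[r0:r1, c0:c1], tile, tile)
            tiles.append(
                Tile(pca, art, lab, origin=(r0, c0),
                     valid=(r1 - r0, c1 - c0))
            )
    return TileSet(tiles, role="all", scene_shape=(h, w))


def split_tiles(
    tiles: TileSet, ratio: float = 0.8, seed: int = 0
) -> tuple[TileSet, TileSet]:
    """Seeded tile-level split: first ``ceil(ratio * n)`` of a shuffled
    order train, the rest test; disjoint and exhaustive."""
    n = len(tiles)
    if n < 2:
        raise ValueError("need at least 2 tiles to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = math.ceil(ratio * n)
    train = [tiles[i] for i in order[:n_train]]
    test = [tiles[i] for i in order[n_train:]]
    return (
        TileSet(train, role="train", scene_shape=tiles.scene_shape),
        TileSet(test, role="test", scene_shape=tiles.scene_shape),
    )


def save_tiles(tiles: TileSet, path) -> None:
    """Persist a tile set to one compressed container."""
    has_art = tiles.tiles and tiles.tiles[0].artificial is not None
    arrays = {
        "pca": np.stack([t.pca for t in tiles]),
        "labels": np.stack([t.labels for t in tiles]),
        "origins": np.array([t.origin for t in tiles]),
        "valids": np.array([t.valid for t in tiles]),
        "role": np.array(tiles.role),
        "scene_shape": np.array(tiles.scene_shape or (0, 0)),
    }
    if has_art:
        arrays["artificial"] = np.stack([t.artificial for t in tiles])
    np.savez_compressed(path, **arrays)


def load_tiles(path) -> TileSet:
    with np.load(path) as npz:
        pca = npz["pca"]
        labels = npz["labels"]
        origins = npz["origins"]
        valids = npz["valids"]
        role = str(npz["role"])
        shape = tuple(int(v) for v in npz["scene_shape"])
        art = npz["artificial"] if "artificial" in npz else None
    tiles = [
        Tile(
            pca[i],
            art[i] if art is not None else None,
            labels[i],
            tuple(int(v) for v in origins[i]),
            tuple(int(v) for v in valids[i]),
        )
        for i in range(len(pca))
    ]
    return TileSet(tiles, role=role,
                   scene_shape=shape if shape != (0, 0) else None)


def mosaic_labels(
    tiles: list[Tile],
    per_tile_labels: list[np.ndarray],
    scene_shape: tuple[int, int],
) -> np.ndarray:
    """Reassemble per-tile label rasters into the scene grid, stripping
    padding; positions not covered by any tile stay 0."""
    out = np.zeros(scene_shape, dtype=np.int32)
    for tile, lab in zip(tiles, per_tile_labels):
        vh, vw = tile.valid
        r0, c0 = tile.origin
        out[r0:r0 + vh, c0:c0 + vw] = lab[:vh, :vw]
    return out
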