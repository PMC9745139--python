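"""The hand-crafted feature branch: NDVI, GLCM textures, Sobel edges.

The branch stacks six channels in a fixed order —
``[ndvi, glcm_homogeneity, glcm_mean, glcm_dissimilarity, glcm_entropy,
sobel_magnitude]`` — NDVI computed from the raw cube's red/NIR bands, the
texture and edge maps from the first principal-component image.

GLCM features come from a sliding window (3x3 by default): for every
pixel, gray-level pairs at the configured offsets are accumulated into a
symmetric co-occurrence distribution P(i, j) over the pairs falling
inside the window, and summarized as

    homogeneity   = sum P / (1 + |i - j|^2)
    mean          = sum i * P_marginal(i)
    dissimilarity = sum P * |i - j|
    entropy       = -sum P * ln P          (over cells with P > 0)

Borders of every sliding operation use reflect padding so feature rasters
stay pixel-aligned with the cube.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import correlate

from .io import select_band_by_wavelength
from .preprocess import PCAModel, apply_pca
from .types import FEATURE_CHANNEL_NAMES, FeatureStack, SpectralCube

__all__ = [
    "compute_ndvi",
    "quantize_gray",
    "glcm_window_features",
    "glcm_map",
    "sobel_edges",
    "build_artificial_stack",
    "SOBEL_X",
    "SOBEL_Y",
    "DEFAULT_OFFSETS",
]

#: Transverse and longitudinal Sobel factors, applied as cross-correlation.
SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float)

#: Four symmetric co-occurrence offsets (0°, 90°, 45°, 135°), averaged.
DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def compute_ndvi(
    cube: SpectralCube, nir_nm: float = 800.0, red_nm: float = 670.0
) -> np.ndarray:
    """Normalized difference vegetation index, (NIR - R) / (NIR + R).

    Positive over vegetation (strong NIR reflectance, chlorophyll red
    absorption), negative over water/snow/cloud, and defined as 0 where
    NIR + R == 0 (the rock / bare-soil convention, where the two bands
    are in balance). Bands are chosen by nearest wavelength.
    """
    nir = cube.data[:, :, select_band_by_wavelength(cube, nir_nm)]
    red = cube.data[:, :, select_band_by_wavelength(cube, red_nm)]
    nir = nir.astype(np.float64)
    red = red.astype(np.float64)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(denom == 0, 0.0, (nir - red) / np.where(
            denom == 0, 1.0, denom))
    return ndvi


def quantize_gray(image: np.ndarray, levels: int = 16) -> np.ndarray:
    """Min-max linear binning of a gray image into ``levels`` bins.

    The output is an integer map in ``[0, levels)``; a constant image maps
    to bin 0.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.isfinite(image).all():
        raise ValueError("image must be finite")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros(image.shape, dtype=np.int32)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.int32)
    return np.clip(q, 0, levels - 1)


def glcm_window_features(
    window: np.ndarray,
    levels: int = 16,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
) -> tuple[float, float, float, float]:
    """Co-occurrence features of a single quantized window.

    Accumulates symmetric pair counts over all in-window pixel pairs at
    the given offsets, normalizes to a distribution, and returns
    ``(homogeneity, mean, dissimilarity, entropy)``.
    """
    window = np.asarray(window)
    if not np.issubdtype(window.dtype, np.integer):
        raise ValueError("window must be quantized to integer gray levels")
    if not offsets:
        raise ValueError("need at least one offset")
    h, w = window.shape
    p = np.zeros((levels, levels), dtype=np.float64)
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), h - max(0, dr)
        c0, c1 = max(0, -dc), w - max(0, dc)
        a = window[r0:r1, c0:c1]
        b = window[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        for i, j in zip(a.ravel(), b.ravel()):
            p[i, j] += 1.0
            p[j, i] += 1.0
    total = p.sum()
    if total == 0:
        raise ValueError("window has no valid pixel pairs at these offsets")
    p /= total
    i_idx, j_idx = np.indices((levels, levels))
    diff = np.abs(i_idx - j_idx)
    homogeneity = float((p / (1.0 + diff**2)).sum())
    dissimilarity = float((p * diff).sum())
    mean = float((np.arange(levels) * p.sum(axis=1)).sum())
    pos = p[p > 0]
    entropy = float(-(pos * np.log(pos)).sum())
    return homogeneity, mean, dissimilarity, entropy


def _pair_slots(
    padded: np.ndarray,
    h: int,
    w: int,
    pad: int,
    offsets: tuple[tuple[int, int], ...],
) -> tuple[np.ndarray, np.ndarray]:
    """All in-window pixel pairs for every window at once.

    Returns two ``(K, H, W)`` integer arrays: slot ``t`` of pixel ``(r,c)``
    holds the gray levels of the ``t``-th pair inside that pixel's window.
    """
    first, second = [], []
    for dr, dc in offsets:
        a_rows = [a for a in range(-pad, pad + 1) if -pad <= a + dr <= pad]
        a_cols = [b for b in range(-pad, pad + 1) if -pad <= b + dc <= pad]
        for a in a_rows:
            for b in a_cols:
                first.append(padded[pad + a: pad + a + h,
                                    pad + b: pad + b + w])
                second.append(padded[pad + a + dr: pad + a + dr + h,
                                     pad + b + dc: pad + b + dc + w])
    return np.stack(first), np.stack(second)


def glcm_map(
    image: np.ndarray,
    window: int = 3,
    levels: int = 16,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    chunk_rows: int = 64,
) -> np.ndarray:
    """Sliding-window GLCM features for every pixel.

    Equivalent to calling :func:`glcm_window_features` on the reflect-
    padded ``window x window`` neighborhood of each pixel, but vectorized:
    each window's pair multiset is materialized once, and the four
    statistics are computed from per-slot pair values. Returns ``H x W x 4``
    in the order ``[homogeneity, mean, dissimilarity, entropy]``.
    """
    image = np.asarray(image)
    if not np.issubdtype(image.dtype, np.integer):
        raise ValueError("image must be quantized to integer gray levels "
                         "(see quantize_gray)")
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be odd and at least 3")
    pad = window // 2  # pairs never leave the window: radius padding is enough
    h, w = image.shape
    padded = np.pad(image, pad, mode="reflect")
    i_vals, j_vals = _pair_slots(padded, h, w, pad, offsets)
    k = i_vals.shape[0]

    diff = np.abs(i_vals - j_vals).astype(np.float64)
    homogeneity = (1.0 / (1.0 + diff**2)).mean(axis=0)
    dissimilarity = diff.mean(axis=0)
    mean = 0.5 * (i_vals + j_vals).mean(axis=0)

    # entropy needs each pair's multiplicity within its window
    codes = (np.minimum(i_vals, j_vals).astype(np.int32) * levels
             + np.maximum(i_vals, j_vals)).transpose(1, 2, 0)  # H, W, K
    diag = (i_vals == j_vals).transpose(1, 2, 0)
    entropy = np.empty((h, w), dtype=np.float64)
    for r0 in range(0, h, chunk_rows):
        r1 = min(r0 + chunk_rows, h)
        c = codes[r0:r1]
        mult = (c[:, :, :, None] == c[:, :, None, :]).sum(axis=3)
        # each slot contributes -(1/K) * ln(P of its cell); off-diagonal
        # codes occupy two symmetric cells with half the mass each
        cell_p = np.where(diag[r0:r1], mult / k, mult / (2.0 * k))
        entropy[r0:r1] = -np.log(cell_p).sum(axis=2) / k
    return np.stack([homogeneity, mean, dissimilarity, entropy], axis=-1)


def sobel_edges(image: np.ndarray) -> np.ndarray:
    """Gradient magnitude from the two 3x3 Sobel factors.

    The kernels are applied as cross-correlation (directional difference
    masks, no 180-degree flip) with reflect padding; the output is
    ``sqrt(gx^2 + gy^2)``.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.isfinite(image).all():
        raise ValueError("image must be finite")
    # scipy's "mirror" is edge-excluding reflection, matching np.pad reflect
    gx = correlate(image, SOBEL_X, mode="mirror")
    gy = correlate(image, SOBEL_Y, mode="mirror")
    return np.hypot(gx, gy)


def _minmax(channel: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    lo, hi = float(channel.min()), float(channel.max())
    if hi == lo:
        return np.zeros_like(channel), (lo, lo + 1.0)
    return (channel - lo) / (hi - lo), (lo, hi)


def build_artificial_stack(
    cube: SpectralCube,
    pca_model: PCAModel,
    nir_nm: float = 800.0,
    red_nm: float = 670.0,
    levels: int = 16,
    window: int = 3,
    source_component: int = 0,
) -> FeatureStack:
    """Assemble the six-channel hand-crafted input.

    NDVI comes from the raw cube; the GLCM maps and Sobel magnitude from
    one principal-component image (PC1 by default, which carries most of
    the variance), rescaled to ``[0, 1]`` first. Every channel is then
    min-max normalized to ``[0, 1]`` with the affine map recorded.
    """
    ndvi = compute_ndvi(cube, nir_nm=nir_nm, red_nm=red_nm)
    scores = apply_pca(cube, pca_model)
    pc = scores.data[:, :, source_component].astype(np.float64)
    pc_unit, _ = _minmax(pc)
    glcm = glcm_map(quantize_gray(pc_unit, levels=levels), window=window,
                    levels=levels)
    sobel = sobel_edges(pc_unit)

    raw = [ndvi, glcm[:, :, 0], glcm[:, :, 1], glcm[:, :, 2],
           glcm[:, :, 3], sobel]
    channels, records = [], []
    for r in raw:
        c, rec = _minmax(r)
        channels.append(c)
        records.append(rec)
    data = np.stack(channels, axis=-1).astype(np.float32)
    return FeatureStack(data, FEATURE_CHANNEL_NAMES, records)
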