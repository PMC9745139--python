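"""Core in-memory containers shared across the pipeline.

Conventions: rasters are row-major with origin at the top-left and
``(row, col)`` indexing; spectral cubes are band-last ``H x W x B``
(interleave conversion happens only at the I/O boundary); class ids are
dense positive integers starting at 1, with 0 reserved for "unlabeled".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectralCube", "ClassScheme", "LabelMap", "FeatureStack"]

#: Canonical channel order of the hand-crafted feature branch.
FEATURE_CHANNEL_NAMES = (
    "ndvi",
    "glcm_homogeneity",
    "glcm_mean",
    "glcm_dissimilarity",
    "glcm_entropy",
    "sobel_magnitude",
)


@dataclass
class SpectralCube:
    """A hyperspectral reflectance image.

    Parameters
    ----------
    data
        ``H x W x B`` array of reflectance (dimensionless, typically in
        ``[0, 1]``) or, after PCA, component scores.
    wavelengths
        Band-center wavelengths in nm, strictly increasing, one per band.
        ``None`` when the bands are not spectral (e.g. principal
        components); wavelength-dependent operations then fail explicitly.
    nodata_mask
        Optional ``H x W`` boolean mask, ``True`` where pixels are invalid.
    """

    data: np.ndarray
    wavelengths: np.ndarray | None = None
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"cube data must be H x W x B, got shape {self.data.shape}"
            )
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=float)
            if self.wavelengths.ndim != 1:
                raise ValueError("wavelengths must be one-dimensional")
            if len(self.wavelengths) != self.n_bands:
                raise ValueError(
                    f"band axis has {self.n_bands} bands but "
                    f"{len(self.wavelengths)} wavelengths were given"
                )
            if np.any(np.diff(self.wavelengths) <= 0):
                raise ValueError("wavelengths must be strictly increasing")
        if self.nodata_mask is not None:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.shape:
                raise ValueError("nodata_mask must be H x W")

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape ``(H, W)``."""
        return self.data.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def require_wavelengths(self) -> np.ndarray:
        if self.wavelengths is None:
            raise ValueError(
                "this cube has no wavelength metadata; supply band indices "
                "explicitly or attach wavelengths"
            )
        return self.wavelengths


@dataclass
class ClassScheme:
    """Mapping from class ids to names and to first-level groups.

    Ids must be dense from 1. ``groups`` assigns every class to a
    first-level category (e.g. Forest, Waters) used for grouped metrics.
    """

    classes: dict[int, str]
    groups: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = sorted(self.classes)
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"class ids must be dense from 1, got {ids}")
        if not self.groups:
            # default: each class is its own group
            self.groups = {i: name for i, name in self.classes.items()}
        missing = set(self.classes) - set(self.groups)
        if missing:
            raise ValueError(f"classes without a group: {sorted(missing)}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def ids(self) -> list[int]:
        return sorted(self.classes)

    @property
    def group_names(self) -> list[str]:
        """Group names in order of first appearance by class id."""
        seen: list[str] = []
        for i in self.ids:
            g = self.groups[i]
            if g not in seen:
                seen.append(g)
        return seen

    @classmethod
    def generic(cls, n_classes: int) -> "ClassScheme":
        return cls({i: f"class_{i}" for i in range(1, n_classes + 1)})


@dataclass
class LabelMap:
    """``H x W`` integer class ids; 0 means unlabeled."""

    labels: np.ndarray
    scheme: ClassScheme

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be H x W")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.scheme.classes)
        if unknown:
            raise ValueError(
                f"labels {sorted(unknown)} do not appear in the class scheme"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class FeatureStack:
    """``H x W x 6`` stack of hand-crafted features in canonical order.

    ``normalization`` records the per-channel affine map applied to bring
    each raw feature into ``[0, 1]``: ``raw = lo + normalized * (hi - lo)``.
    """

    data: np.ndarray
    channel_names: tuple[str, ...] = FEATURE_CHANNEL_NAMES
    normalization: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("feature stack must be H x W x C")
        if self.data.shape[2] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[2]} channels but "
                f"{len(self.channel_names)} channel names"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, :, self.channel_names.index(name)]

    def raw_channel(self, name: str) -> np.ndarray:
        """Channel with its recorded normalization undone."""
        idx = self.channel_names.index(name)
        if self.normalization is None:
            return self.data[:, :, idx]
        lo, hi = self.normalization[idx]
        return lo + self.data[:, :, idx] * (hi - lo)
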