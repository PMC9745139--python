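"""Synthetic labelled hyperspectral scenes.

Generates scenes with the statistical structure real airborne vegetation
imagery exhibits and that the downstream method relies on: per-class
smooth, strongly inter-band-correlated endmember spectra; vegetation
classes with a red edge (NIR reflectance well above red), water with the
opposite sign; contiguous irregular class regions; class-dependent
multiplicative spatial texture; additive sensor noise.

A single global seed fans out to independent per-stage child seeds
(endmembers, class map, texture, noise) so each stage can be regenerated
on its own and the whole scene is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import ClassScheme, LabelMap, SpectralCube

__all__ = [
    "SceneSpec",
    "Endmember",
    "generate_endmembers",
    "generate_class_map",
    "render_scene",
    "generate_scene",
]

VALID_KINDS = ("vegetation", "water", "bare", "built")

# wavelength landmarks (nm) used for spectral shapes and sign checks
RED_BAND = (620.0, 690.0)
NIR_BAND = (760.0, 960.0)
RED_EDGE_NM = 720.0


@dataclass
class SceneSpec:
    """Parameters of a synthetic scene.

    Defaults describe the desk-scale study condition: a 256x256 scene with
    32 bands over 400-1000 nm and 5 classes (three vegetation, one water,
    one bare), 0.5% additive noise and 5% multiplicative texture. The
    noise level is calibrated so adjacent-band correlation stays above
    0.9, the inter-band redundancy the PCA step presumes.
    """

    height: int = 256
    width: int = 256
    n_bands: int = 32
    wavelength_range: tuple[float, float] = (400.0, 1000.0)
    n_classes: int = 5
    class_kinds: tuple[str, ...] | None = None
    noise_sigma: float = 0.005
    texture_amplitude: float = 0.05
    illumination_amplitude: float = 0.10
    blob_smoothness: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands < 8:
            raise ValueError("n_bands must be at least 8")
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        if self.height < 32 or self.width < 32:
            raise ValueError("height and width must be at least 32")
        lo, hi = self.wavelength_range
        if not lo < hi:
            raise ValueError("wavelength_range must be increasing")
        if self.class_kinds is None:
            # default rotation biased toward vegetation, with one water
            # class so NDVI carries sign information
            base = ["vegetation", "water", "vegetation", "bare", "vegetation",
                    "built", "vegetation", "bare"]
            self.class_kinds = tuple(
                base[i % len(base)] for i in range(self.n_classes)
            )
        self.class_kinds = tuple(self.class_kinds)
        if len(self.class_kinds) != self.n_classes:
            raise ValueError("class_kinds must have one entry per class")
        for k in self.class_kinds:
            if k not in VALID_KINDS:
                raise ValueError(f"unknown class kind {k!r}")

    @property
    def wavelengths(self) -> np.ndarray:
        lo, hi = self.wavelength_range
        return np.linspace(lo, hi, self.n_bands)

    def child_seed(self, stage: str) -> np.random.SeedSequence:
        """Deterministic per-stage seed derived from the global seed."""
        stages = ("endmembers", "class_map", "texture", "noise",
                  "illumination")
        return np.random.SeedSequence(
            entropy=self.seed, spawn_key=(stages.index(stage),)
        )

    def scheme(self) -> ClassScheme:
        names = {}
        counts: dict[str, int] = {}
        for i, kind in enumerate(self.class_kinds, start=1):
            counts[kind] = counts.get(kind, 0) + 1
            names[i] = f"{kind}_{counts[kind]}"
        groups = {
            i: kind for i, kind in enumerate(self.class_kinds, start=1)
        }
        return ClassScheme(names, groups)


@dataclass
class Endmember:
    """Pure spectral signature of one land-cover class."""

    class_id: int
    kind: str
    spectrum: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if self.spectrum.min() < 0 or self.spectrum.max() > 1:
            raise ValueError("endmember reflectance must lie in [0, 1]")


def _band_mean(spectrum: np.ndarray, wl: np.ndarray,
               band: tuple[float, float]) -> float:
    sel = (wl >= band[0]) & (wl <= band[1])
    if not sel.any():  # coarse grids: fall back to the nearest band
        sel = np.zeros_like(sel)
        sel[np.argmin(np.abs(wl - 0.5 * (band[0] + band[1])))] = True
    return float(spectrum[sel].mean())


def spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle (radians) between two spectra viewed as vectors."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.arccos(cosang))


def _base_spectrum(kind: str, wl: np.ndarray, rng: np.random.Generator
                   ) -> np.ndarray:
    """Smooth archetype spectrum for a land-cover kind, jittered per class."""
    x = wl
    if kind == "vegetation":
        # chlorophyll well in the red, green bump, logistic red edge to a
        # NIR plateau; plateau height, edge position/steepness and the
        # visible level all vary so vegetation classes stay separable
        vis_scale = rng.uniform(0.6, 1.6)
        vis = vis_scale * (0.05 + 0.05 * np.exp(-((x - 550) / 55.0) ** 2))
        vis -= vis_scale * 0.03 * np.exp(-((x - 670) / 55.0) ** 2)
        nir_level = rng.uniform(0.25, 0.7)
        edge_pos = rng.uniform(705.0, 730.0)
        # the edge must be resolved by the band grid: steeper-than-spacing
        # transitions would decorrelate adjacent bands, which real
        # contiguous-band sensors do not show
        spacing = float(x[1] - x[0])
        edge_width = rng.uniform(1.5, 2.5) * max(14.0, 1.4 * spacing)
        edge = 1.0 / (1.0 + np.exp(-(x - edge_pos) / edge_width))
        spec = vis * (1 - edge) + nir_level * edge
        spec -= rng.uniform(0.0, 0.12) * nir_level * \
            np.exp(-((x - 960) / max(50.0, 2 * spacing)) ** 2)
    elif kind == "water":
        # reflectance decays with wavelength; near-zero in the NIR
        peak = rng.uniform(0.06, 0.12)
        spec = peak * np.exp(-(x - x[0]) / rng.uniform(150.0, 250.0)) + 0.01
    elif kind == "bare":
        # soils brighten gently toward longer wavelengths
        lo, hi = rng.uniform(0.10, 0.18), rng.uniform(0.28, 0.40)
        spec = lo + (hi - lo) * (x - x[0]) / (x[-1] - x[0])
    else:  # built
        level = rng.uniform(0.18, 0.32)
        spec = level + 0.02 * np.sin((x - x[0]) / 180.0)
    return spec


def generate_endmembers(
    spec: SceneSpec, min_angle: float = 0.05, max_tries: int = 50
) -> list[Endmember]:
    """One smooth endmember per class, pairwise separated in spectral angle.

    Spectra are archetypes per kind plus a few low-amplitude Gaussian bumps
    for within-kind diversity. Vegetation endmembers are guaranteed a red
    edge (NIR mean > red mean), water the opposite. Raises if ``n_classes``
    spectra cannot be separated by ``min_angle`` radians.
    """
    wl = spec.wavelengths
    rng = np.random.default_rng(spec.child_seed("endmembers"))
    members: list[Endmember] = []
    for cid, kind in enumerate(spec.class_kinds, start=1):
        for attempt in range(max_tries):
            base = _base_spectrum(kind, wl, rng)
            n_bumps = rng.integers(1, 4)
            for _ in range(n_bumps):
                center = rng.uniform(wl[0], wl[-1])
                width = rng.uniform(60.0, 150.0)
                amp = rng.uniform(-0.03, 0.03)
                base = base + amp * np.exp(-((wl - center) / width) ** 2)
            base = np.clip(base, 0.01, 0.99)
            red = _band_mean(base, wl, RED_BAND)
            nir = _band_mean(base, wl, NIR_BAND)
            if kind == "vegetation" and not nir > red:
                continue
            if kind == "water" and not nir < red:
                continue
            if all(spectral_angle(base, m.spectrum) >= min_angle
                   for m in members):
                members.append(Endmember(cid, kind, base))
                break
        else:
            raise ValueError(
                f"could not separate {spec.n_classes} endmembers by a "
                f"spectral angle of {min_angle} rad; reduce n_classes or "
                f"min_angle"
            )
    return members


def generate_class_map(spec: SceneSpec) -> LabelMap:
    """Contiguous irregular class regions via smoothed-noise argmax.

    One Gaussian random field per class is smoothed at length scale
    ``blob_smoothness``; each pixel takes the class whose field is largest,
    producing interlocking blobs. Every class id ``1..n_classes`` is
    guaranteed present (a small disc is planted for any class the argmax
    missed, which only happens for many classes on small scenes).
    """
    rng = np.random.default_rng(spec.child_seed("class_map"))
    h, w = spec.height, spec.width
    fields = rng.standard_normal((spec.n_classes, h, w))
    for c in range(spec.n_classes):
        f = gaussian_filter(fields[c], sigma=spec.blob_smoothness,
                            mode="reflect")
        fields[c] = (f - f.mean()) / (f.std() + 1e-12)
    labels = np.argmax(fields, axis=0).astype(np.int32) + 1

    missing = set(range(1, spec.n_classes + 1)) - set(np.unique(labels))
    if missing:
        rr, cc = np.mgrid[0:h, 0:w]
        radius = max(4.0, spec.blob_smoothness / 2.0)
        for cid in sorted(missing):
            cy = rng.integers(int(radius), h - int(radius))
            cx = rng.integers(int(radius), w - int(radius))
            disc = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
            labels[disc] = cid
    return LabelMap(labels, spec.scheme())


def _texture_fields(spec: SceneSpec,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-class zero-mean, unit-std smoothed noise; correlation length
    varies by class so co-occurrence texture statistics separate classes."""
    h, w = spec.height, spec.width
    fields = np.empty((spec.n_classes, h, w))
    for c in range(spec.n_classes):
        sigma = 0.8 + 1.1 * (c % 4)  # class-dependent texture scale
        f = gaussian_filter(rng.standard_normal((h, w)), sigma=sigma,
                            mode="reflect")
        fields[c] = (f - f.mean()) / (f.std() + 1e-12)
    return fields


def render_scene(
    spec: SceneSpec,
    endmembers: list[Endmember],
    class_map: LabelMap,
) -> SpectralCube:
    """Render the reflectance cube from endmembers and the class map.

    Each pixel's spectrum is its class endmember modulated by a spectrally
    flat multiplicative texture field (class-dependent correlation length,
    amplitude ``texture_amplitude``) plus iid Gaussian noise of standard
    deviation ``noise_sigma`` per band, clipped to ``[0, 1]``.
    """
    if class_map.shape != (spec.height, spec.width):
        raise ValueError("class map shape does not match scene spec")
    if len(endmembers) != spec.n_classes:
        raise ValueError("need one endmember per class")
    wl = spec.wavelengths
    spectra = np.stack([m.spectrum for m in
                        sorted(endmembers, key=lambda m: m.class_id)])
    if spectra.shape[1] != spec.n_bands:
        raise ValueError("endmember band count does not match scene spec")

    labels = class_map.labels
    cube = spectra[labels - 1]  # H x W x B

    if spec.illumination_amplitude > 0:
        # smooth scene-wide brightness field (sun angle, topography):
        # common to all bands, it reproduces the strong inter-band
        # redundancy real reflectance cubes show
        illum_rng = np.random.default_rng(spec.child_seed("illumination"))
        g = gaussian_filter(
            illum_rng.standard_normal((spec.height, spec.width)),
            sigma=16.0, mode="reflect")
        g = (g - g.mean()) / (g.std() + 1e-12)
        cube = cube * (1.0 + spec.illumination_amplitude * g[:, :, None])
    if spec.texture_amplitude > 0:
        tex_rng = np.random.default_rng(spec.child_seed("texture"))
        fields = _texture_fields(spec, tex_rng)
        pixel_tex = np.take_along_axis(
            fields, (labels - 1)[None], axis=0
        )[0]
        cube = cube * (1.0 + spec.texture_amplitude * pixel_tex[:, :, None])
    if spec.noise_sigma > 0:
        noise_rng = np.random.default_rng(spec.child_seed("noise"))
        cube = cube + noise_rng.normal(
            0.0, spec.noise_sigma, size=cube.shape
        )
    cube = np.clip(cube, 0.0, 1.0)
    return SpectralCube(cube.astype(np.float32), wavelengths=wl)


def generate_scene(
    spec: SceneSpec,
) -> tuple[SpectralCube, LabelMap, list[Endmember]]:
    """Convenience wrapper: endmembers + class map + rendered cube."""
    members = generate_endmembers(spec)
    class_map = generate_class_map(spec)
    cube = render_scene(spec, members, class_map)
    return cube, class_map, members
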