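"""Readers and writers for hyperspectral cubes and label rasters.

Three cube formats are supported: an ``.npz`` container (the native
fixture format, keys ``data``/``wavelengths``/optionally ``labels``),
ENVI header + flat binary (BSQ/BIL/BIP interleaves, wavelengths in the
header), and GeoTIFF via tifffile (bands as pages, wavelengths carried in
a JSON image description). All readers and writers are exact round trips
for their native dtype, never reorder bands, and deliver the canonical
band-last ``H x W x B`` layout.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .types import ClassScheme, LabelMap, SpectralCube

__all__ = [
    "read_cube",
    "write_cube",
    "read_labels",
    "write_labels",
    "select_band_by_wavelength",
]

# ENVI "data type" codes <-> numpy dtypes (the commonly used subset)
_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
    5: np.float64, 12: np.uint16, 13: np.uint32,
}
_DTYPE_TO_ENVI = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format.lower()
    suffix = path.suffix.lower()
    if suffix == ".npz":
        return "npz"
    if suffix in (".tif", ".tiff"):
        return "gtiff"
    if suffix in (".hdr", ".img", ".bsq", ".bil", ".bip", ".raw", ""):
        return "envi"
    raise ValueError(f"cannot infer format from {path.name!r}")


# ---------------------------------------------------------------------------
# ENVI header + binary

def _envi_header_path(path: Path) -> Path:
    if path.suffix.lower() == ".hdr":
        return path
    return path.with_suffix(path.suffix + ".hdr")


def _parse_envi_header(text: str) -> dict[str, str]:
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic line)")
    fields: dict[str, str] = {}
    lines = iter(text.splitlines())
    next(lines)  # magic
    for line in lines:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and not value.endswith("}"):
            parts = [value]
            for cont in lines:
                parts.append(cont)
                if cont.strip().endswith("}"):
                    break
            value = " ".join(parts)
        fields[key] = value
    return fields


def _parse_envi_list(value: str) -> list[float]:
    return [float(v) for v in value.strip().strip("{}").split(",") if v.strip()]


def _read_envi(path: Path) -> SpectralCube:
    hdr_path = _envi_header_path(path)
    if not hdr_path.exists():
        raise FileNotFoundError(f"ENVI header not found: {hdr_path}")
    hdr = _parse_envi_header(hdr_path.read_text())
    samples = int(hdr["samples"])  # width
    lines_ = int(hdr["lines"])  # height
    bands = int(hdr["bands"])
    interleave = hdr.get("interleave", "bsq").lower()
    dtype = _ENVI_DTYPES[int(hdr["data type"])]
    byte_order = int(hdr.get("byte order", 0))

    data_path = path if path != hdr_path else path.with_suffix("")
    if not data_path.exists():
        raise FileNotFoundError(f"ENVI binary not found: {data_path}")
    raw = np.fromfile(data_path, dtype=dtype)
    if byte_order == 1:
        raw = raw.byteswap()
    expected = samples * lines_ * bands
    if raw.size != expected:
        raise ValueError(
            f"ENVI binary holds {raw.size} values but the header implies "
            f"{lines_} lines x {samples} samples x {bands} bands"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, lines_, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines_, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines_, samples, bands)
    else:
        raise ValueError(f"unknown ENVI interleave {interleave!r}")

    wavelengths = None
    if "wavelength" in hdr:
        wl = _parse_envi_list(hdr["wavelength"])
        if len(wl) != bands:
            raise ValueError(
                f"header lists {len(wl)} wavelengths for {bands} bands"
            )
        wavelengths = np.asarray(wl)
    else:
        warnings.warn(
            "ENVI header has no wavelength field; wavelength-dependent "
            "operations on this cube will fail", stacklevel=3,
        )
    return SpectralCube(np.ascontiguousarray(cube), wavelengths=wavelengths)


def _write_envi(cube: SpectralCube, path: Path, interleave: str = "bsq"
                ) -> None:
    interleave = interleave.lower()
    data = cube.data
    h, w = cube.shape
    b = cube.n_bands
    if interleave == "bsq":
        flat = data.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = data.transpose(0, 2, 1)
    elif interleave == "bip":
        flat = data
    else:
        raise ValueError(f"unknown ENVI interleave {interleave!r}")
    dtype = np.dtype(data.dtype)
    if dtype not in _DTYPE_TO_ENVI:
        raise ValueError(f"dtype {dtype} has no ENVI data type code")
    np.ascontiguousarray(flat).tofile(path)
    lines = [
        "ENVI",
        "description = {hsiseg export}",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {b}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_TO_ENVI[dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if cube.wavelengths is not None:
        wl = ", ".join(f"{v:.4f}" for v in cube.wavelengths)
        lines.append("wavelength units = Nanometers")
        lines.append(f"wavelength = {{ {wl} }}")
    _envi_header_path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GeoTIFF (tifffile) and npz

def _read_gtiff(path: Path) -> SpectralCube:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description
    if arr.ndim == 2:
        arr = arr[None]
    # tifffile yields band-first for multi-page / planar rasters
    cube = np.moveaxis(arr, 0, -1)
    wavelengths = None
    if desc:
        try:
            meta = json.loads(desc)
            if "wavelengths" in meta:
                wavelengths = np.asarray(meta["wavelengths"], dtype=float)
        except (json.JSONDecodeError, TypeError):
            pass
    if wavelengths is None:
        warnings.warn(
            "GeoTIFF carries no wavelength metadata; wavelength-dependent "
            "operations on this cube will fail", stacklevel=3,
        )
    return SpectralCube(np.ascontiguousarray(cube), wavelengths=wavelengths)


def _write_gtiff(cube: SpectralCube, path: Path) -> None:
    import tifffile

    meta = {}
    if cube.wavelengths is not None:
        meta["wavelengths"] = [float(v) for v in cube.wavelengths]
    tifffile.imwrite(
        path,
        np.moveaxis(cube.data, -1, 0),
        description=json.dumps(meta),
    )


def read_cube(path: str | Path, format: str | None = None) -> SpectralCube:
    """Read a hyperspectral cube; format inferred from the suffix if not
    given (``npz``, ``envi`` or ``gtiff``)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "npz":
        with np.load(path) as npz:
            data = npz["data"]
            wavelengths = npz["wavelengths"] if "wavelengths" in npz else None
        if wavelengths is None:
            warnings.warn(
                "npz container has no wavelengths; wavelength-dependent "
                "operations on this cube will fail", stacklevel=2,
            )
        return SpectralCube(data, wavelengths=wavelengths)
    if fmt == "envi":
        return _read_envi(path)
    if fmt == "gtiff":
        return _read_gtiff(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_cube(cube: SpectralCube, path: str | Path,
               format: str | None = None, interleave: str = "bsq") -> None:
    """Write a cube in ``npz``, ``envi`` (choosing the interleave) or
    ``gtiff`` format; the inverse of :func:`read_cube`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "npz":
        arrays = {"data": cube.data}
        if cube.wavelengths is not None:
            arrays["wavelengths"] = cube.wavelengths
        np.savez_compressed(path, **arrays)
    elif fmt == "envi":
        _write_envi(cube, path, interleave=interleave)
    elif fmt == "gtiff":
        _write_gtiff(cube, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Label rasters

def read_labels(path: str | Path, scheme: ClassScheme | None = None
                ) -> LabelMap:
    """Read a single-band integer raster (GeoTIFF or PNG) as a label map.

    ``scheme`` defaults to a generic scheme covering the ids present.
    Floating-point rasters are rejected: labels must be integral.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported label raster {path.name!r}")
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError("label raster must be single-band")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(
            f"label raster must be integral, got dtype {arr.dtype}"
        )
    if scheme is None:
        n = int(arr.max(initial=0))
        scheme = ClassScheme.generic(max(n, 1))
    return LabelMap(arr.astype(np.int32), scheme)


def write_labels(labels: LabelMap, path: str | Path) -> None:
    path = Path(path)
    arr = labels.labels
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr.astype(np.int32))
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        if arr.max(initial=0) > 65535:
            raise ValueError("PNG labels limited to 16-bit ids")
        dtype = np.uint8 if arr.max(initial=0) < 256 else np.uint16
        iio.imwrite(path, arr.astype(dtype))
    else:
        raise ValueError(f"unsupported label raster {path.name!r}")


def select_band_by_wavelength(
    cube: SpectralCube, target_nm: float, tolerance_nm: float = 50.0
) -> int:
    """Index of the band nearest ``target_nm``; ties go to the lower index.

    Raises when even the nearest band is farther than the effective
    tolerance — ``tolerance_nm`` widened to half the local band spacing on
    coarse grids, so nearest-band selection inside the covered range never
    fails, while requests beyond the spectral range still do.
    """
    wl = cube.require_wavelengths()
    dist = np.abs(wl - target_nm)
    idx = int(np.argmin(dist))  # argmin takes the first (lower) index on ties
    spacing = np.diff(wl)
    half_local = 0.5 * float(
        spacing[min(max(idx - 1, 0), len(spacing) - 1):idx + 1].max()
    ) if len(spacing) else 0.0
    if dist[idx] > max(tolerance_nm, half_local):
        raise ValueError(
            f"no band within {tolerance_nm} nm of {target_nm} nm "
            f"(nearest is {wl[idx]:.1f} nm)"
        )
    return idx
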