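"""Multiband raster and mask I/O with sensor band-role mapping.

Scenes are height x width x bands arrays of unitless real values (digital
numbers or reflectance -- the downstream indices are scale-covariant after
normalization).  Band roles map the semantic bands the burn indices need
(red, near-infrared, mid-infrared) onto the file's band order; presets are
provided for Landsat 5 TM and Landsat 8 OLI numbering.

Supported formats: (Geo)TIFF via tifffile, and plain ``.npy`` arrays for
fixtures.  GeoTIFF georeferencing tags are carried opaquely: read as raw
TIFF tag values and copied verbatim onto written masks, never interpreted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = [
    "BandRoles",
    "Scene",
    "sensor_roles",
    "read_scene",
    "write_scene",
    "write_mask",
    "read_mask",
]

# GeoTIFF tags carried opaquely (code -> (dtype, name)); enough to round-trip
# ModelPixelScale / ModelTiepoint / ModelTransformation / GeoKey directories.
_GEO_TAGS = {
    33550: "ModelPixelScaleTag",
    33922: "ModelTiepointTag",
    34264: "ModelTransformationTag",
    34735: "GeoKeyDirectoryTag",
    34736: "GeoDoubleParamsTag",
    34737: "GeoAsciiParamsTag",
}
_GEO_DTYPES = {
    33550: "d",
    33922: "d",
    34264: "d",
    34735: "H",
    34736: "d",
    34737: "s",
}


@dataclass(frozen=True)
class BandRoles:
    """Semantic band assignment, 0-based indices into the band axis.

    ``cva_bands`` lists the bands entering the change-vector magnitude.
    """

    red: int
    nir: int
    mir: int
    cva_bands: tuple[int, ...]

    def validate(self, n_bands: int) -> None:
        indices = [self.red, self.nir, self.mir]
        if len(set(indices)) != 3:
            raise ValueError(f"band roles must be distinct, got {indices}")
        for idx in [*indices, *self.cva_bands]:
            if not 0 <= idx < n_bands:
                raise ValueError(
                    f"band index {idx} outside [0, {n_bands}) for this raster"
                )
        if len(self.cva_bands) == 0:
            raise ValueError("cva_bands must not be empty")


def sensor_roles(sensor: str) -> BandRoles:
    """Band-role preset for a named sensor.

    ``"tm"``  : Landsat 5 TM  -- red=band 3, NIR=band 4, mid-IR=band 7,
                CVA over the six reflective bands 1-5 and 7.
    ``"oli"`` : Landsat 8 OLI -- red=band 4, NIR=band 5, mid-IR=band 7
                (SWIR2, the standard NBR pairing), CVA over bands 2-7.

    Indices returned are 0-based positions assuming the file stacks exactly
    those reflective bands in order (TM: 1,2,3,4,5,7; OLI: 2,3,4,5,6,7).
    """
    sensor = sensor.lower()
    if sensor == "tm":
        # stacked order: b1,b2,b3,b4,b5,b7 -> positions 0..5
        return BandRoles(red=2, nir=3, mir=5, cva_bands=(0, 1, 2, 3, 4, 5))
    if sensor == "oli":
        # stacked order: b2,b3,b4,b5,b6,b7 -> positions 0..5
        return BandRoles(red=2, nir=3, mir=5, cva_bands=(0, 1, 2, 3, 4, 5))
    raise ValueError(f"unknown sensor preset {sensor!r}; use 'tm', 'oli' or custom roles")


@dataclass
class Scene:
    """One multiband acquisition: pixels (H, W, B), roles, optional nodata/georef."""

    pixels: np.ndarray
    band_roles: BandRoles
    nodata_value: float | None = None
    georef: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise ValueError("scene pixels must be (height, width, bands)")
        self.band_roles.validate(self.pixels.shape[2])

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.pixels.shape[2]

    def band(self, index: int) -> np.ndarray:
        return self.pixels[:, :, index]

    @property
    def red(self) -> np.ndarray:
        return self.band(self.band_roles.red)

    @property
    def nir(self) -> np.ndarray:
        return self.band(self.band_roles.nir)

    @property
    def mir(self) -> np.ndarray:
        return self.band(self.band_roles.mir)

    def valid_mask(self) -> np.ndarray:
        """True where a pixel is valid in every band (finite, not nodata)."""
        valid = np.all(np.isfinite(self.pixels), axis=2)
        if self.nodata_value is not None:
            valid &= ~np.any(self.pixels == self.nodata_value, axis=2)
        return valid

    def with_pixels(self, pixels: np.ndarray) -> "Scene":
        return replace(self, pixels=pixels)


def _read_geo_tags(page: "tifffile.TiffPage") -> dict:
    geo = {}
    for code in _GEO_TAGS:
        tag = page.tags.get(code)
        if tag is not None:
            geo[code] = tag.value
    return geo


def _geo_extratags(georef: dict) -> list:
    extratags = []
    for code, value in georef.items():
        dtype = _GEO_DTYPES.get(code)
        if dtype is None:
            continue
        if dtype == "s":
            extratags.append((code, "s", 0, value, True))
        else:
            arr = np.atleast_1d(np.asarray(value)).ravel()
            if dtype == "H":
                arr = arr.astype(np.uint16)
            extratags.append((code, dtype, arr.size, tuple(arr.tolist()), True))
    return extratags


def _load_array(path: str) -> tuple[np.ndarray, dict]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".npy":
        return np.load(path), {}
    if ext in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            geo = _read_geo_tags(tif.pages[0])
        return data, geo
    raise ValueError(f"unsupported raster format: {path!r} (use .tif/.tiff/.npy)")


def read_scene(
    path: str,
    roles: BandRoles,
    nodata_value: float | None = None,
) -> Scene:
    """Read a multiband raster into a Scene.

    TIFF band axes are accepted either band-first (B, H, W) or band-last
    (H, W, B); band-first is assumed whenever the first axis is the smallest,
    matching how multiband GeoTIFFs are normally written.
    """
    data, geo = _load_array(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[:, :, None]
    elif data.ndim == 3 and data.shape[0] <= min(data.shape[1], data.shape[2]):
        data = np.moveaxis(data, 0, -1)
    return Scene(pixels=data.astype(float), band_roles=roles,
                 nodata_value=nodata_value, georef=geo)


def write_scene(path: str, scene: Scene) -> None:
    """Write a Scene as band-first TIFF (or .npy), preserving georef tags."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".npy":
        np.save(path, scene.pixels)
        return
    data = np.moveaxis(scene.pixels, -1, 0).astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack",
                     extratags=_geo_extratags(scene.georef))


def write_mask(path: str, mask: np.ndarray, georef: dict | None = None) -> None:
    """Write a binary {0,1} mask as uint8 TIFF or .npy, copying georef tags."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be in {0, 1}")
    ext = os.path.splitext(path)[1].lower()
    if ext == ".npy":
        np.save(path, mask.astype(np.uint8))
        return
    tifffile.imwrite(path, mask.astype(np.uint8), photometric="minisblack",
                     extratags=_geo_extratags(georef or {}))


def read_mask(path: str) -> np.ndarray:
    """Read a binary mask written by :func:`write_mask`."""
    data, _ = _load_array(path)
    return np.asarray(data).astype(np.uint8)
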