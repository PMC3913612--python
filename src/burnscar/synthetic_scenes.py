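"""Synthetic bi-temporal burn scenes with known ground truth.

Real post-fire Landsat imagery shows a characteristic spectral shift inside
the scar: a strong drop in near-infrared reflectance (destroyed leaf
structure) with moderate rises in the red and mid-infrared bands (exposed
char and soil, reduced canopy water).  The generator emulates this pattern
on a multiband pair:

* a pre-fire background of vegetation and soil patches, each class with a
  per-band mean and standard deviation;
* a burn region drawn as a thresholded smoothed Gaussian random field --
  cheap to generate, and naturally irregular with concave, blurred edges;
* a post-fire scene equal to the pre-fire scene plus the per-band burn
  shift inside the scar (feathered across the blurred edge) plus
  independent temporal noise everywhere.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .raster_io import BandRoles, Scene

__all__ = ["SceneSpec", "make_burn_pair", "make_disk_image", "CLUTTER_SHIFT_EXAMPLE"]

# TM-like 6-band layout (stacked reflective bands); values on a DN-like scale.
_DEFAULT_ROLES = BandRoles(red=2, nir=3, mir=5, cva_bands=(0, 1, 2, 3, 4, 5))

# per-band (mean, sd) for the two background classes, bands in stacked order
# blue-ish, green, red, NIR, SWIR1, SWIR2
_VEG_SPECTRUM = ((60.0, 4.0), (55.0, 4.0), (45.0, 4.0), (160.0, 8.0), (90.0, 6.0), (50.0, 5.0))
_SOIL_SPECTRUM = ((80.0, 5.0), (85.0, 5.0), (95.0, 6.0), (120.0, 7.0), (140.0, 8.0), (110.0, 7.0))

# additive post-fire change inside the scar: NIR strongly down, red and
# mid-IR up, other bands mildly perturbed
_DEFAULT_BURN_SHIFT = (-5.0, -8.0, 12.0, -60.0, 10.0, 25.0)

# example per-band amplitude for spatially correlated non-fire temporal
# change (soil moisture, phenology): same spectral sign pattern as burning
# but much weaker, so drying patches mimic low-severity burn; off by default
CLUTTER_SHIFT_EXAMPLE = (-1.0, -2.0, 3.0, -10.0, 3.0, 5.0)


@dataclass(frozen=True)
class SceneSpec:
    """Generator settings; defaults emulate a TM-like burned-forest pair."""

    shape: tuple[int, int] = (128, 128)
    band_roles: BandRoles = _DEFAULT_ROLES
    class_spectra: tuple = (_VEG_SPECTRUM, _SOIL_SPECTRUM)
    burn_shift: tuple = _DEFAULT_BURN_SHIFT
    temporal_noise_sd: float = 15.0
    illumination_gain_range: float = 0.08
    clutter_shift: tuple = (0.0,) * 6
    clutter_smoothness: float = 8.0
    scar_smoothness: float = 2.0
    scar_area_fraction: float = 0.15
    multi_blob: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.scar_area_fraction < 0.5:
            raise ValueError("scar_area_fraction must be in (0, 0.5)")
        if self.temporal_noise_sd < 0 or self.scar_smoothness < 0:
            raise ValueError("noise and smoothness must be >= 0")
        if not 0.0 <= self.illumination_gain_range < 1.0:
            raise ValueError("illumination_gain_range must be in [0, 1)")
        n_bands = len(self.burn_shift)
        if len(self.clutter_shift) != n_bands:
            raise ValueError("clutter_shift and burn_shift band counts differ")
        for spec in self.class_spectra:
            if len(spec) != n_bands:
                raise ValueError("class_spectra and burn_shift band counts differ")
            if any(sd < 0 for _, sd in spec):
                raise ValueError("class SDs must be >= 0")

    @property
    def n_bands(self) -> int:
        return len(self.burn_shift)

    def with_seed(self, seed: int) -> "SceneSpec":
        return replace(self, seed=seed)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return (field - field.mean()) / (field.std() + 1e-12)


def _scar_mask(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    """Irregular burn blob(s) near the target area fraction, one component
    by default (largest connected component of the thresholded field)."""
    h, w = spec.shape
    sigma = max(min(h, w) / 8.0, 2.0)
    for _ in range(100):
        field = _smooth_field(rng, spec.shape, sigma)
        # bias the field toward the image center so the scar avoids borders
        yy, xx = np.mgrid[0:h, 0:w]
        r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
        field = field - 1.2 * r2
        thresh = np.quantile(field, 1.0 - spec.scar_area_fraction * 1.3)
        mask = field > thresh
        labels, n = ndimage.label(mask)
        if n == 0:
            continue
        if not spec.multi_blob:
            sizes = ndimage.sum(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
        frac = mask.mean()
        if 0.5 * spec.scar_area_fraction <= frac <= 1.5 * spec.scar_area_fraction:
            return mask.astype(np.uint8)
    raise RuntimeError("could not draw a scar at the requested area fraction")


def _background(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    """Patchy vegetation/soil class map plus per-band Gaussian noise."""
    h, w = spec.shape
    n_classes = len(spec.class_spectra)
    class_field = _smooth_field(rng, spec.shape, max(min(h, w) / 10.0, 2.0))
    # vegetation dominates: split at a high quantile of the class field
    edges = np.quantile(class_field, np.linspace(0.7, 1.0, n_classes + 1)[1:-1])
    class_map = np.digitize(class_field, edges)
    pixels = np.zeros((h, w, spec.n_bands))
    for ci, spectrum in enumerate(spec.class_spectra):
        sel = class_map == ci
        for bi, (mean, sd) in enumerate(spectrum):
            band = pixels[:, :, bi]
            band[sel] = mean + sd * rng.standard_normal(int(sel.sum()))
    return pixels


def make_burn_pair(spec: SceneSpec | None = None) -> tuple[Scene, Scene, np.ndarray]:
    """Generate (pre, post, truth): a bi-temporal pair with a known scar.

    The burn shift is feathered through a Gaussian blur of the truth mask
    (radius ``scar_smoothness``) so the scar edge is gradual, like the
    blurred boundaries of real scars; the binary truth stays the unblurred
    mask.  The post scene additionally carries three kinds of non-fire
    temporal change, emulating an uncorrected digital-number pair: a
    per-band multiplicative gain difference (sun angle / atmosphere,
    uniform in [1-r, 1+r] with r = ``illumination_gain_range``), an
    optional smooth clutter field (``clutter_smoothness``) scaled by
    ``clutter_shift`` -- patchy moisture/phenology change whose positive
    phase mimics a weak burn signature -- and white per-pixel noise.
    """
    spec = spec or SceneSpec()
    rng = np.random.default_rng(spec.seed)
    pre_pixels = _background(rng, spec)
    truth = _scar_mask(rng, spec)
    feather = (
        ndimage.gaussian_filter(truth.astype(float), spec.scar_smoothness)
        if spec.scar_smoothness > 0 else truth.astype(float)
    )
    shift = np.asarray(spec.burn_shift)
    post_pixels = pre_pixels + feather[:, :, None] * shift[None, None, :]
    if spec.illumination_gain_range > 0:
        gains = 1.0 + rng.uniform(-spec.illumination_gain_range,
                                  spec.illumination_gain_range, spec.n_bands)
        post_pixels = post_pixels * gains[None, None, :]
    if any(a != 0 for a in spec.clutter_shift):
        clutter = _smooth_field(rng, spec.shape, spec.clutter_smoothness)
        post_pixels = post_pixels + clutter[:, :, None] * np.asarray(spec.clutter_shift)
    post_pixels = post_pixels + spec.temporal_noise_sd * rng.standard_normal(post_pixels.shape)
    pre = Scene(pixels=pre_pixels, band_roles=spec.band_roles)
    post = Scene(pixels=post_pixels, band_roles=spec.band_roles)
    return pre, post, truth


def make_disk_image(
    shape: tuple[int, int] = (64, 64),
    inside_value: float = 0.8,
    outside_value: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 0,
    radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Centered disk on a constant background: the unit fixture for the
    level-set solver.  Returns (image, truth)."""
    if inside_value == outside_value:
        raise ValueError("inside and outside values must differ")
    h, w = shape
    r = radius if radius is not None else min(h, w) / 4.0
    yy, xx = np.mgrid[0:h, 0:w]
    truth = (((yy - (h - 1) / 2.0) ** 2 + (xx - (w - 1) / 2.0) ** 2) <= r * r)
    img = np.where(truth, inside_value, outside_value).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + noise_sd * rng.standard_normal(img.shape)
    return img, truth.astype(np.uint8)
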