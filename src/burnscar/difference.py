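"""Fused difference image from a bi-temporal scene pair.

Three per-pixel change signals are combined: the change-vector magnitude
(Euclidean norm of the spectral difference over the CVA bands), the NDVI
difference and the NBR difference.  Each is min-max normalized to [0, 1]
and the three are averaged with weights proportional to their standard
deviations, so the component carrying the strongest change signal dominates;
the result is renormalized to [0, 1].

Differences are taken pre minus post, so burned vegetation -- whose NIR
falls and red/mid-IR rise -- shows up bright in every component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_io import Scene

__all__ = [
    "DifferenceProduct",
    "SeparabilityReport",
    "cva_magnitude",
    "ndvi",
    "nbr",
    "index_difference",
    "minmax_normalize",
    "fuse",
    "fused_difference",
    "separability",
]

HIST_BINS = 64  # fixed equal-width binning on [0,1] for separability reports


@dataclass
class DifferenceProduct:
    """Fused difference image plus its normalized components and weights."""

    di: np.ndarray
    d_cva: np.ndarray
    d_ndvi: np.ndarray
    d_nbr: np.ndarray
    weights: np.ndarray  # (w_cva, w_ndvi, w_nbr), non-negative, sums to 1


@dataclass
class SeparabilityReport:
    """Normalized-distance diagnostic between burn and unburn pixel values.

    ``d_value`` = |mean_burn - mean_unburn| / (sd_burn + sd_unburn); larger
    means better class separation.  ``overlap_fraction`` is the shared area
    of the two class histograms (normalized), in [0, 1].
    """

    d_value: float
    burn_mean: float
    unburn_mean: float
    burn_sd: float
    unburn_sd: float
    histograms: dict
    overlap_fraction: float

    def to_dict(self) -> dict:
        return {
            "d_value": self.d_value,
            "burn_mean": self.burn_mean,
            "unburn_mean": self.unburn_mean,
            "burn_sd": self.burn_sd,
            "unburn_sd": self.unburn_sd,
            "overlap_fraction": self.overlap_fraction,
            "histograms": {k: np.asarray(v).tolist() for k, v in self.histograms.items()},
        }


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def cva_magnitude(pre: Scene, post: Scene) -> np.ndarray:
    """Per-pixel Euclidean magnitude of the spectral change vector.

    The norm runs over ``band_roles.cva_bands``, which must agree between
    the two dates.
    """
    if pre.shape != post.shape or pre.n_bands != post.n_bands:
        raise ValueError("pre and post scenes must share shape and band count")
    if pre.band_roles.cva_bands != post.band_roles.cva_bands:
        raise ValueError("cva_bands must be identical between dates")
    bands = list(pre.band_roles.cva_bands)
    if not bands:
        raise ValueError("cva_bands is empty")
    diff = post.pixels[:, :, bands] - pre.pixels[:, :, bands]
    return np.sqrt(np.sum(diff * diff, axis=2))


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den != 0)
    return np.clip(out, -1.0, 1.0)


def ndvi(scene: Scene) -> np.ndarray:
    """(NIR - red) / (NIR + red), clipped to [-1, 1]; 0 where the sum is 0."""
    nir, red = scene.nir, scene.red
    return _safe_ratio(nir - red, nir + red)


def nbr(scene: Scene) -> np.ndarray:
    """(NIR - midIR) / (NIR + midIR), same guards as :func:`ndvi`."""
    nir, mir = scene.nir, scene.mir
    return _safe_ratio(nir - mir, nir + mir)


def index_difference(pre_index: np.ndarray, post_index: np.ndarray) -> np.ndarray:
    """Pre minus post, so an index drop (burned vegetation) is positive."""
    _check_same_shape(pre_index, post_index)
    return pre_index - post_index


def minmax_normalize(g: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Rescale to [0, 1] by (g - min) / (max - min); constant grids map to 0."""
    g = np.asarray(g, dtype=float)
    vals = g[valid] if valid is not None else g
    lo, hi = float(np.min(vals)), float(np.max(vals))
    if hi == lo:
        return np.zeros_like(g)
    return (g - lo) / (hi - lo)


def fuse(
    d_cva: np.ndarray,
    d_ndvi: np.ndarray,
    d_nbr: np.ndarray,
    valid: np.ndarray | None = None,
) -> DifferenceProduct:
    """SD-weighted fusion of the three normalized difference components.

    Weights are each component's standard deviation over valid pixels,
    normalized to sum to 1; the weighted sum is min-max rescaled to [0, 1].
    Raises if all three components are constant (no change signal at all).
    """
    _check_same_shape(d_cva, d_ndvi)
    _check_same_shape(d_cva, d_nbr)
    comps = [np.asarray(c, dtype=float) for c in (d_cva, d_ndvi, d_nbr)]
    sds = np.array([
        float(np.std(c[valid] if valid is not None else c)) for c in comps
    ])
    total = sds.sum()
    if total == 0:
        raise ValueError("all difference components are constant: no change signal")
    weights = sds / total
    di = sum(w * c for w, c in zip(weights, comps))
    di = minmax_normalize(di, valid)
    return DifferenceProduct(di=di, d_cva=comps[0], d_ndvi=comps[1],
                             d_nbr=comps[2], weights=weights)


def fused_difference(pre: Scene, post: Scene) -> DifferenceProduct:
    """Full difference pipeline: components, normalization and fusion."""
    valid = pre.valid_mask() & post.valid_mask()
    use_valid = None if valid.all() else valid
    d_cva = minmax_normalize(cva_magnitude(pre, post), use_valid)
    d_ndvi = minmax_normalize(index_difference(ndvi(pre), ndvi(post)), use_valid)
    d_nbr = minmax_normalize(index_difference(nbr(pre), nbr(post)), use_valid)
    return fuse(d_cva, d_ndvi, d_nbr, use_valid)


def separability(
    di: np.ndarray,
    truth: np.ndarray,
    valid: np.ndarray | None = None,
) -> SeparabilityReport:
    """Burn/unburn normalized distance and histogram overlap on a grid."""
    di = np.asarray(di, dtype=float)
    truth = np.asarray(truth).astype(bool)
    _check_same_shape(di, truth)
    if valid is None:
        valid = np.ones_like(truth, dtype=bool)
    burn = di[truth & valid]
    unburn = di[~truth & valid]
    if burn.size == 0 or unburn.size == 0:
        raise ValueError("both burn and unburn classes must be non-empty")
    mu_b, mu_u = float(burn.mean()), float(unburn.mean())
    sd_b, sd_u = float(burn.std()), float(unburn.std())
    if sd_b + sd_u == 0:
        raise ValueError("degenerate classes: zero total standard deviation")
    d_value = abs(mu_b - mu_u) / (sd_b + sd_u)

    edges = np.linspace(0.0, 1.0, HIST_BINS + 1)
    h_b, _ = np.histogram(np.clip(burn, 0, 1), bins=edges)
    h_u, _ = np.histogram(np.clip(unburn, 0, 1), bins=edges)
    p_b = h_b / h_b.sum()
    p_u = h_u / h_u.sum()
    overlap = float(np.minimum(p_b, p_u).sum())
    return SeparabilityReport(
        d_value=d_value, burn_mean=mu_b, unburn_mean=mu_u,
        burn_sd=sd_b, unburn_sd=sd_u,
        histograms={"bin_edges": edges, "burn": h_b, "unburn": h_u},
        overlap_fraction=overlap,
    )
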