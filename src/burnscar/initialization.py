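"""Automatic initial contour for the level-set segmentation.

Between two cloud-free acquisitions of the same area, unchanged pixels keep
a nearly linear relation between their NIR values, so the date-2 NIR band is
regressed on the date-1 NIR band by ordinary least squares.  Pixels whose
squared residual, scaled by the residual variance (a one-dimensional
Mahalanobis distance), is large are change candidates; a 2-class K-means on
those error values supplies the change/no-change threshold without any
user-set constant.  The change mask becomes the initial level-set surface
as a binary step (+c inside, -c outside).

A tiled-rectangles initialization is also provided as the traditional
baseline starting contour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from .raster_io import Scene

__all__ = [
    "RegressionFit",
    "InitialContour",
    "fit_nir",
    "fitting_error",
    "kmeans_split",
    "auto_initial_contour",
    "rectangle_initial_contour",
]

PHI_STEP = 2.0  # magnitude of the binary-step initial surface


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    residual_variance: float


@dataclass
class InitialContour:
    mask: np.ndarray           # uint8, 1 = change / inside
    phi0: np.ndarray           # +PHI_STEP on mask, -PHI_STEP elsewhere
    source: str                # "auto" or "rectangles"


def fit_nir(x1: np.ndarray, x2: np.ndarray) -> RegressionFit:
    """OLS fit x2 ~ slope * x1 + intercept over all pixels.

    slope = cov(x1, x2) / var(x1); residual_variance is the mean squared
    residual of the fit.
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x1.shape != x2.shape:
        raise ValueError("x1 and x2 must share shape")
    var1 = float(np.var(x1))
    if var1 == 0:
        raise ValueError("date-1 band is constant: regression undefined")
    slope = float(np.cov(x1, x2, bias=True)[0, 1] / var1)
    intercept = float(np.mean(x2) - slope * np.mean(x1))
    resid = x2 - slope * x1 - intercept
    return RegressionFit(slope=slope, intercept=intercept,
                         residual_variance=float(np.mean(resid * resid)))


def fitting_error(x1: np.ndarray, x2: np.ndarray, fit: RegressionFit) -> np.ndarray:
    """Squared regression residual scaled by the residual variance.

    The scaling makes the error invariant to jointly rescaling both bands;
    it is a squared Mahalanobis distance in one dimension.
    """
    if fit.residual_variance <= 0:
        raise ValueError(
            "zero residual variance: the two dates fit perfectly (no-change scene)"
        )
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    resid = x2 - fit.slope * x1 - fit.intercept
    return resid * resid / fit.residual_variance


def kmeans_split(values: np.ndarray, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """2-class K-means on scalar values; centers returned sorted ascending.

    Labels are relative to the sorted centers (label 1 = higher center).
    On one-dimensional data the optimal 2-partition is an interval split of
    the sorted values, so the global within-cluster-SSE optimum is found
    exactly by scanning all splits; no Lloyd iterations and no dependence
    on the seed (kept for interface stability).
    """
    values = np.asarray(values, dtype=float).ravel()
    if np.unique(values).size < 2:
        raise ValueError("need at least 2 distinct values to split")
    v = np.sort(values)
    n = v.size
    csum = np.cumsum(v)
    csq = np.cumsum(v * v)
    i = np.arange(1, n)  # split: v[:i] low cluster, v[i:] high cluster
    sse_lo = csq[i - 1] - csum[i - 1] ** 2 / i
    sum_hi = csum[-1] - csum[i - 1]
    sse_hi = (csq[-1] - csq[i - 1]) - sum_hi ** 2 / (n - i)
    sse = sse_lo + sse_hi
    # only boundaries between distinct values induce a valid partition
    valid = v[i] > v[i - 1]
    sse[~valid] = np.inf
    k = int(i[np.argmin(sse)])
    thresh = 0.5 * (v[k - 1] + v[k])
    labels = (values > thresh).astype(int)
    centers = np.array([values[labels == 0].mean(), values[labels == 1].mean()])
    return labels, centers


def _binary_phi(mask: np.ndarray) -> np.ndarray:
    return np.where(mask.astype(bool), PHI_STEP, -PHI_STEP)


def auto_initial_contour(pre: Scene, post: Scene, seed: int = 0) -> InitialContour:
    """Change mask from K-means on NIR fitting errors, as a level-set start."""
    if pre.shape != post.shape:
        raise ValueError("scenes must share shape")
    x1, x2 = pre.nir, post.nir
    fit = fit_nir(x1, x2)
    err = fitting_error(x1, x2, fit)
    labels, _ = kmeans_split(err.ravel(), seed=seed)
    mask = (labels == 1).reshape(err.shape).astype(np.uint8)
    return InitialContour(mask=mask, phi0=_binary_phi(mask), source="auto")


def rectangle_initial_contour(shape: tuple[int, int], spacing: int = 16) -> InitialContour:
    """Periodic grid of rectangles tiling the image, the traditional start.

    Each spacing x spacing cell holds one centered rectangle of half the
    cell size, so both phases are present everywhere in the image.
    """
    h, w = shape
    if spacing < 4 or spacing >= min(h, w):
        raise ValueError(f"spacing must be in [4, min(h, w)), got {spacing}")
    rows = np.arange(h) % spacing
    cols = np.arange(w) % spacing
    lo, hi = spacing // 4, spacing - spacing // 4
    in_r = (rows >= lo) & (rows < hi)
    in_c = (cols >= lo) & (cols < hi)
    mask = (in_r[:, None] & in_c[None, :]).astype(np.uint8)
    return InitialContour(mask=mask, phi0=_binary_phi(mask), source="rectangles")
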