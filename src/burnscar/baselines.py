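"""Comparison methods: Otsu thresholding, fuzzy C-means, traditional C-V.

The traditional Chan-Vese configuration (TCV) differs from the proposed
pipeline in both of its inputs: the difference image is the change-vector
magnitude alone (no index fusion) and the initial contour is the tiled
rectangle grid rather than the regression-derived change mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chanvese import CVParams, SegmentationResult, orient_bright, segment
from .difference import cva_magnitude, minmax_normalize
from .initialization import rectangle_initial_contour
from .raster_io import Scene

__all__ = ["FcmParams", "TCV_PARAMS", "otsu_threshold", "fcm_segment", "tcv_segment"]

# The rectangle-tiling start spends a long time near the symmetric c1 = c2
# saddle; under a strong length penalty the seed rectangles vanish by
# curvature flow before the data term can differentiate the phases.  The
# baseline therefore runs at the strongest smoothing it tolerates.
TCV_PARAMS = CVParams(mu=0.01)


@dataclass(frozen=True)
class FcmParams:
    """Fuzzy C-means settings: fuzzifier m, convergence tol, budget, seed."""

    m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m <= 1 or self.tol <= 0 or self.max_iter < 1:
            raise ValueError("require m > 1, tol > 0, max_iter >= 1")


def otsu_threshold(g: np.ndarray, bins: int = 256) -> tuple[float, np.ndarray]:
    """Threshold maximizing between-class variance over a histogram of g.

    The grid is binned into ``bins`` equal-width bins over its own range;
    returns (threshold, mask) with mask = g > threshold.
    """
    g = np.asarray(g, dtype=float)
    if np.unique(g).size < 2:
        raise ValueError("constant grid has no threshold")
    counts, edges = np.histogram(g.ravel(), bins=bins)
    p = counts / counts.sum()
    mids = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    mu_cum = np.cumsum(p * mids)
    mu_total = mu_cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.nan_to_num(between, nan=-np.inf)
    k = int(np.argmax(between[:-1]))  # cut after bin k
    threshold = float(edges[k + 1])
    return threshold, (g > threshold).astype(np.uint8)


def fcm_segment(g: np.ndarray, params: FcmParams | None = None) -> np.ndarray:
    """2-cluster fuzzy C-means on pixel intensities.

    Minimizes sum_ik u_ik^m ||x_i - v_k||^2 subject to sum_k u_ik = 1 by the
    standard alternating membership/center updates.  The mask selects pixels
    whose membership to the higher-center cluster exceeds 0.5.
    """
    params = params or FcmParams()
    g = np.asarray(g, dtype=float)
    x = g.ravel()
    if np.unique(x).size < 2:
        raise ValueError("constant grid cannot be clustered")
    # deterministic spread-out start; imbalanced intensity data collapses
    # onto the majority mode if both centers start near the median
    centers = np.quantile(x, [0.10, 0.90])
    if centers[0] == centers[1]:
        centers = np.array([x.min(), x.max()], dtype=float)
    u = None
    prev_obj = np.inf
    for _ in range(params.max_iter):
        d2 = (x[:, None] - centers[None, :]) ** 2
        d2 = np.maximum(d2, 1e-300)
        inv = d2 ** (-1.0 / (params.m - 1.0))  # = d^{-2/(m-1)}
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u ** params.m
        centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        obj = float((um * d2).sum())
        if abs(prev_obj - obj) <= params.tol * max(1.0, abs(prev_obj)):
            break
        prev_obj = obj
    hi = int(np.argmax(centers))
    mask = (u[:, hi] > 0.5).reshape(g.shape)
    return mask.astype(np.uint8)


def tcv_segment(
    pre: Scene,
    post: Scene,
    params: CVParams | None = None,
    spacing: int = 16,
) -> SegmentationResult:
    """Traditional C-V: CVA-only difference image, rectangle initial contour.

    The mask is oriented so the burn class is the brighter phase of the
    difference image (the symmetric energy does not fix the labeling).
    """
    di = minmax_normalize(cva_magnitude(pre, post))
    init = rectangle_initial_contour(di.shape, spacing=spacing)
    result = segment(di, init.phi0, params or TCV_PARAMS)
    result.mask = orient_bright(result.mask, di)
    return result
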