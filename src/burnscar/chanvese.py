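"""Chan-Vese region-based level-set segmentation.

The model partitions an image u0 into two regions of approximately constant
intensity by evolving a level-set surface phi whose zero level is the
contour.  The energy is

    E(phi, c1, c2) = mu * Length + nu * Area(inside)
                   + lambda1 * sum_inside (u0 - c1)^2
                   + lambda2 * sum_outside (u0 - c2)^2

with the inside/outside indicator smoothed by a regularized Heaviside
H_eps(z) = 1/2 (1 + (2/pi) arctan(z/eps)) and its derivative
delta_eps(z) = eps / (pi (eps^2 + z^2)).  c1, c2 are the H_eps-weighted
region means, optimal for fixed phi.  phi evolves by explicit gradient
descent

    phi += dt * delta_eps(phi) * [mu * kappa - nu
                                  - lambda1 (u0 - c1)^2 + lambda2 (u0 - c2)^2]

where kappa = div(grad phi / |grad phi|) is the contour curvature computed
by central finite differences with replicate borders.  Because delta_eps
localizes the update near the contour, phi need not stay a signed-distance
function and no reinitialization is performed; a binary-step start works.

Evolution stops when the fraction of pixels whose sign changed over a
trailing window of iterations falls below a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CVParams",
    "LevelSetState",
    "SegmentationResult",
    "heaviside_eps",
    "dirac_eps",
    "region_means",
    "curvature",
    "evolve_step",
    "energy",
    "segment",
]

CURV_ETA = 1e-8  # |grad phi| regularization in the curvature denominator


@dataclass(frozen=True)
class CVParams:
    """Chan-Vese tuning constants.

    mu       : contour-length penalty weight (>= 0); larger = smoother contour.
    min_iter : patience for motion onset: until the cumulative flipped
               fraction reaches ``min_activity``, a quiet window alone does
               not stop the run before this many iterations.  From a
               binary-step start the surface needs a warm-up descent to
               reach the zero level, during which no sign can flip; a
               rectangle start additionally idles near the symmetric
               c1 = c2 saddle before the phases separate.
    min_activity : cumulative fraction of pixels that must have flipped at
               least once before the flip-fraction rule is trusted on its
               own (the contour has demonstrably moved).
    nu       : inside-area penalty (any sign; 0 disables).
    lambda1/2: data-fidelity weights for inside/outside (> 0).
    epsilon  : Heaviside/Dirac regularization width, in phi units (> 0).
    dt       : explicit time step (> 0); stability requires mu*dt modest.
    max_iter : iteration budget.
    tol      : stop when the sign-change fraction over the window drops below.
    stop_window: trailing window length (iterations) for the stopping rule.
    """

    mu: float = 0.1
    nu: float = 0.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    epsilon: float = 1.0
    dt: float = 0.5
    max_iter: int = 6000
    tol: float = 1e-4
    stop_window: int = 30
    min_iter: int = 2000
    min_activity: float = 0.02

    def __post_init__(self) -> None:
        if self.mu < 0 or self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("mu must be >= 0 and lambda1, lambda2 > 0")
        if self.epsilon <= 0 or self.dt < 0:
            raise ValueError("epsilon must be > 0 and dt >= 0")
        if (self.max_iter < 1 or self.tol < 0 or self.stop_window < 1
                or self.min_iter < 0 or self.min_activity < 0):
            raise ValueError("invalid stopping parameters")


@dataclass
class LevelSetState:
    phi: np.ndarray
    c1: float = 0.0
    c2: float = 0.0
    iteration: int = 0
    energy_trace: list = field(default_factory=list)


@dataclass
class SegmentationResult:
    mask: np.ndarray
    iterations: int
    converged: bool
    energy_trace: list
    phi: np.ndarray


def heaviside_eps(z, epsilon: float):
    """Smoothed unit step: 1/2 (1 + (2/pi) arctan(z/eps))."""
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(np.asarray(z, dtype=float) / epsilon))


def dirac_eps(z, epsilon: float):
    """Smoothed delta, the derivative of heaviside_eps: eps / (pi (eps^2 + z^2))."""
    z = np.asarray(z, dtype=float)
    return (epsilon / np.pi) / (epsilon * epsilon + z * z)


def region_means(u0: np.ndarray, phi: np.ndarray, epsilon: float) -> tuple[float, float]:
    """H_eps-weighted means of u0 inside (phi > 0) and outside the contour."""
    h = heaviside_eps(phi, epsilon)
    w_in = float(h.sum())
    w_out = float((1.0 - h).sum())
    if w_in == 0 or w_out == 0:
        raise ValueError("a region has zero weight; contour degenerate")
    c1 = float((u0 * h).sum() / w_in)
    c2 = float((u0 * (1.0 - h)).sum() / w_out)
    return c1, c2


def _grad_central(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pad = np.pad(phi, 1, mode="edge")
    gy = (pad[2:, 1:-1] - pad[:-2, 1:-1]) / 2.0
    gx = (pad[1:-1, 2:] - pad[1:-1, :-2]) / 2.0
    return gy, gx


def curvature(phi: np.ndarray) -> np.ndarray:
    """div(grad phi / |grad phi|) by central differences, replicate borders."""
    phi = np.asarray(phi, dtype=float)
    if phi.shape[0] < 3 or phi.shape[1] < 3:
        raise ValueError("grid must be at least 3x3")
    gy, gx = _grad_central(phi)
    norm = np.sqrt(gx * gx + gy * gy) + CURV_ETA
    ny, nx = gy / norm, gx / norm
    dny, _ = _grad_central(ny)
    _, dnx = _grad_central(nx)
    return dny + dnx


def energy(u0: np.ndarray, phi: np.ndarray, params: CVParams) -> float:
    """Discrete Chan-Vese energy with c1, c2 at their optimal (mean) values."""
    eps = params.epsilon
    c1, c2 = region_means(u0, phi, eps)
    h = heaviside_eps(phi, eps)
    gy, gx = _grad_central(phi)
    grad_mag = np.sqrt(gx * gx + gy * gy)
    length = float((dirac_eps(phi, eps) * grad_mag).sum())
    area = float(h.sum())
    fid1 = float(((u0 - c1) ** 2 * h).sum())
    fid2 = float(((u0 - c2) ** 2 * (1.0 - h)).sum())
    return params.mu * length + params.nu * area + params.lambda1 * fid1 + params.lambda2 * fid2


def evolve_step(u0: np.ndarray, state: LevelSetState, params: CVParams) -> LevelSetState:
    """One explicit gradient-descent update of phi; returns the state mutated."""
    eps = params.epsilon
    c1, c2 = region_means(u0, state.phi, eps)
    force = (
        params.mu * curvature(state.phi)
        - params.nu
        - params.lambda1 * (u0 - c1) ** 2
        + params.lambda2 * (u0 - c2) ** 2
    )
    phi_new = state.phi + params.dt * dirac_eps(state.phi, eps) * force
    if not np.all(np.isfinite(phi_new)):
        raise FloatingPointError(
            "phi became non-finite during evolution; reduce the time step dt"
        )
    state.phi = phi_new
    state.c1, state.c2 = c1, c2
    state.iteration += 1
    state.energy_trace.append(energy(u0, state.phi, params))
    return state


def orient_bright(mask: np.ndarray, u0: np.ndarray) -> np.ndarray:
    """Relabel so the positive class is the brighter phase of u0.

    With lambda1 == lambda2 and nu == 0 the energy is invariant under
    swapping the two phases, so which one ends up as phi > 0 depends only
    on the starting surface.  A burn scar is by construction the bright
    phase of the difference image; this picks that labeling.
    """
    mask = np.asarray(mask)
    inside = mask.astype(bool)
    if not inside.any() or inside.all():
        return mask
    if u0[inside].mean() < u0[~inside].mean():
        return (1 - mask).astype(mask.dtype)
    return mask


def segment(u0: np.ndarray, phi0: np.ndarray, params: CVParams | None = None) -> SegmentationResult:
    """Evolve phi from phi0 until the contour stabilizes or max_iter.

    Convergence: fraction of pixels whose sign(phi) changed over the last
    ``stop_window`` iterations below ``tol``.  Quiet windows also occur
    before the contour has started moving at all (binary-step warm-up,
    rectangle-start saddle), so until the cumulative flipped fraction
    reaches ``min_activity`` a quiet window only stops the run after
    ``min_iter`` iterations.  Pixels with phi exactly 0 count as outside
    (mask 0).

    phi0 is rescaled to unit maximum magnitude before evolution, so the
    result does not depend on the height of a binary-step start.
    """
    params = params or CVParams()
    u0 = np.asarray(u0, dtype=float)
    phi = np.asarray(phi0, dtype=float).copy()
    if not ((phi > 0).any() and (phi <= 0).any()):
        raise ValueError("phi0 must contain both signs (both phases present)")
    phi /= np.max(np.abs(phi))
    state = LevelSetState(phi=phi)
    n = u0.size
    window_start_mask = state.phi > 0
    converged = False
    ever_flipped = np.zeros_like(window_start_mask)
    for it in range(params.max_iter):
        evolve_step(u0, state, params)
        if (it + 1) % params.stop_window == 0:
            cur = state.phi > 0
            flips = cur != window_start_mask
            ever_flipped |= flips
            changed = np.count_nonzero(flips) / n
            window_start_mask = cur
            moved = ever_flipped.mean() >= params.min_activity
            if changed < params.tol and (moved or (it + 1) >= params.min_iter):
                converged = True
                break
    return SegmentationResult(
        mask=(state.phi > 0).astype(np.uint8),
        iterations=state.iteration,
        converged=converged,
        energy_trace=state.energy_trace,
        phi=state.phi,
    )
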