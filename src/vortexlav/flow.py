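"""Horn-Schunck variational optical flow between consecutive frames.

The flow (u, v) between frames I0 and I1 minimizes the classical energy

    E(u, v) = integral (I_t + I_x u + I_y v)^2 + alpha (|grad u|^2 + |grad v|^2)

combining brightness constancy with spatial smoothness.  The minimizer is
found by the classical Jacobi fixed-point iteration on the Euler-Lagrange
equations,

    u <- ubar - I_x (I_x ubar + I_y vbar + I_t) / (alpha^2 + I_x^2 + I_y^2)

(symmetrically for v), where ubar, vbar are 4-neighbor averages.  The
iteration starts from zero flow and is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

#: 4-neighbor averaging stencil used for ubar / vbar.
_AVG_KERNEL = np.array([[0.0, 0.25, 0.0], [0.25, 0.0, 0.25], [0.0, 0.25, 0.0]])


@dataclass
class FlowField:
    """Per-pixel displacement between two frames, in pixels per frame step.

    ``u`` is the x (column) displacement, ``v`` the y (row) displacement.
    """

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape or self.u.ndim != 2:
            raise ValueError("u and v must be congruent 2D grids")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("flow must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def scaled(self, factor: float) -> "FlowField":
        return FlowField(u=self.u * factor, v=self.v * factor)


@dataclass(frozen=True)
class HsParams:
    """Horn-Schunck solver parameters.

    alpha is the smoothness weight, on the scale of image gradients: the
    default 15 suits 0-255 intensities.  Iteration stops when the mean
    absolute flow update drops below ``tol`` (pixels) or at ``max_iter``.
    The Jacobi iteration propagates flow by diffusion, so per-iteration
    updates shrink long before the flow has converged; the defaults are
    deliberately strict (the update is ~1e-4 px while the recovered
    displacement is still growing by tens of percent).
    """

    alpha: float = 15.0
    max_iter: int = 2000
    tol: float = 1e-5

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")


def image_derivatives(i0: np.ndarray, i1: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spatio-temporal derivatives (Ix, Iy, It) of a frame pair.

    Spatial derivatives are central differences (one-sided at the edges) of
    the temporal average (I0 + I1)/2, which centers them between the two
    frames; It = I1 - I0.
    """
    i0 = np.asarray(i0, dtype=float)
    i1 = np.asarray(i1, dtype=float)
    if i0.shape != i1.shape:
        raise ValueError("frames must share a shape")
    if min(i0.shape) < 3:
        raise ValueError("frames must be at least 3x3")
    mid = 0.5 * (i0 + i1)
    iy, ix = np.gradient(mid)
    it = i1 - i0
    return ix, iy, it


def estimate_hs(i0: np.ndarray, i1: np.ndarray, params: HsParams | None = None) -> FlowField:
    """Estimate dense optical flow from I0 to I1 by Horn-Schunck iteration."""
    params = params or HsParams()
    i0 = np.asarray(i0, dtype=float)
    i1 = np.asarray(i1, dtype=float)
    if not (np.all(np.isfinite(i0)) and np.all(np.isfinite(i1))):
        raise ValueError("input frames must be finite")
    ix, iy, it = image_derivatives(i0, i1)
    denom = params.alpha**2 + ix**2 + iy**2
    u = np.zeros_like(i0)
    v = np.zeros_like(i0)
    for _ in range(params.max_iter):
        ubar = convolve(u, _AVG_KERNEL, mode="nearest")
        vbar = convolve(v, _AVG_KERNEL, mode="nearest")
        common = (ix * ubar + iy * vbar + it) / denom
        u_new = ubar - ix * common
        v_new = vbar - iy * common
        delta = 0.5 * (np.mean(np.abs(u_new - u)) + np.mean(np.abs(v_new - v)))
        u, v = u_new, v_new
        if delta < params.tol:
            break
    return FlowField(u=u, v=v)


def hs_energy(i0: np.ndarray, i1: np.ndarray, flow: FlowField, alpha: float) -> float:
    """Discretized Horn-Schunck energy of a candidate flow.

    Uses the alpha^2 smoothness weighting consistent with the fixed-point
    update; useful for verifying that iterations do not increase the energy.
    """
    ix, iy, it = image_derivatives(i0, i1)
    data = (it + ix * flow.u + iy * flow.v) ** 2
    guy, gux = np.gradient(flow.u)
    gvy, gvx = np.gradient(flow.v)
    smooth = gux**2 + guy**2 + gvx**2 + gvy**2
    return float(np.sum(data) + alpha**2 * np.sum(smooth))
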