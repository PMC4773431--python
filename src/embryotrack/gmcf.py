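"""Geodesic mean curvature flow (GMCF) image filtering.

The filter evolves the image intensity ``u`` under edge-stopped level-set
curvature motion,

    u_t = g(|grad G_sigma * u|) kappa |grad u|  +  grad g . grad u,

where ``g(s) = 1 / (1 + K s^2)`` is the edge indicator evaluated on the
Gaussian-presmoothed gradient.  Homogeneous regions (g ≈ 1) undergo mean
curvature smoothing, which removes speckle noise, while steep edges
(g ≈ 0) are left in place — the flow denoises and can locally sharpen at
the same time.

Numerics: explicit finite differences with anisotropic spacing, reflective
boundaries, the regularized curvature expansion of :mod:`._pde`, an upwinded
advection term, and a per-step min–max limiter that enforces the discrete
maximum principle exactly (the continuous flow never creates new extrema;
the limiter removes the residual overshoot of the explicit scheme).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _pde
from .model import VoxelGrid

__all__ = ["GmcfParams", "edge_indicator", "gmcf_filter"]


@dataclass
class GmcfParams:
    """Parameters of the GMCF filtering stage.

    K : edge-sensitivity coefficient of ``g(s) = 1/(1 + K s^2)``, ≥ 0;
        larger K preserves weaker edges.  K = 0 reduces the flow to pure
        mean curvature motion.
    sigma_pre : standard deviation (µm) of the presmoothing Gaussian used
        only inside the edge indicator.
    n_iter : number of explicit PDE steps (default 5).
    tau : step size in scheme units; ``None`` selects the stability bound.
    """

    K: float = 1.0
    sigma_pre: float = 1.0
    n_iter: int = 5
    tau: float | None = None

    def __post_init__(self):
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.sigma_pre < 0:
            raise ValueError("sigma_pre must be >= 0")
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be > 0")


def edge_indicator(s, K: float):
    """Edge indicator ``g(s) = 1 / (1 + K s^2)`` for gradient magnitude s ≥ 0.

    Equals 1 in flat regions and decreases towards 0 on strong edges.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("gradient magnitude s must be >= 0")
    if K < 0:
        raise ValueError("K must be >= 0")
    return 1.0 / (1.0 + K * s * s)


def gmcf_filter(grid: VoxelGrid, params: GmcfParams) -> VoxelGrid:
    """Denoise one volume by geodesic mean curvature flow.

    Returns a grid of identical geometry; the output range never exceeds the
    input range (discrete maximum principle).  With ``n_iter = 0`` this is
    the identity.
    """
    grid.require_pde_size()
    u = grid.values.copy()
    if params.n_iter == 0:
        return grid.copy_with(u)

    spacing = grid.spacing  # (sz, sy, sx) matches (z, y, x) axis order
    rng = float(u.max() - u.min())
    eps = 1e-4 * rng if rng > 0 else 1e-8

    lo, hi = float(u.min()), float(u.max())
    for _ in range(params.n_iter):
        grad_pre = _pde.presmoothed_gradient_mag(u, spacing, params.sigma_pre)
        g = edge_indicator(grad_pre, params.K)
        grad_g = _pde.central_gradients(g, spacing)
        vmax = max(float(np.abs(c).max()) for c in grad_g)
        tau = params.tau
        if tau is None:
            tau = _pde.stable_tau(spacing, diffusion_max=1.0, velocity_max=vmax)
        rhs = g * _pde.curvature_motion(u, spacing, eps)
        if params.K > 0:
            rhs = rhs + _pde.upwind_advection(u, grad_g, spacing)
        u = u + tau * rhs
        _pde.check_stable(u, lo, hi, "gmcf_filter", tau)
        np.clip(u, lo, hi, out=u)  # min–max limiter
    return grid.copy_with(u)
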