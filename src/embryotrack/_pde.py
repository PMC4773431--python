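"""Finite-difference building blocks for the level-set PDE stages.

All operators work on ``(z, y, x)`` arrays with anisotropic voxel spacing
``(sz, sy, sx)`` in µm and reflective (zero-flux Neumann) boundaries, which
``np.pad(mode="edge")`` realises as one-sided constant extension.

The curvature-motion term uses the regularized level-set expansion

    kappa |grad u|_eps = [ sum_i u_ii (Q - u_i^2) - 2 sum_{i<j} u_i u_j u_ij ] / Q

with ``Q = |grad u|^2 + eps^2``: for small ``eps`` this is mean-curvature
motion of the intensity level sets, for large ``eps`` it degenerates to the
Laplacian (linear diffusion), which is exactly the regularization knob the
subjective-surface model exposes.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "central_gradients",
    "second_derivatives",
    "curvature_motion",
    "upwind_grad_mag",
    "upwind_advection",
    "presmoothed_gradient_mag",
    "stable_tau",
    "check_stable",
]


def _shift(u: np.ndarray, axis: int, offset: int) -> np.ndarray:
    """Neighbour values along ``axis`` with edge replication (Neumann)."""
    padded = np.pad(u, [(1, 1) if a == axis else (0, 0) for a in range(u.ndim)],
                    mode="edge")
    sl = [slice(None)] * u.ndim
    sl[axis] = slice(1 + offset, 1 + offset + u.shape[axis])
    return padded[tuple(sl)]


def central_gradients(u: np.ndarray, spacing) -> list[np.ndarray]:
    """First derivatives along (z, y, x) by central differences."""
    return [
        (_shift(u, ax, +1) - _shift(u, ax, -1)) / (2.0 * spacing[ax])
        for ax in range(3)
    ]


def forward_diff(u: np.ndarray, axis: int, h: float) -> np.ndarray:
    return (_shift(u, axis, +1) - u) / h


def backward_diff(u: np.ndarray, axis: int, h: float) -> np.ndarray:
    return (u - _shift(u, axis, -1)) / h


def second_derivatives(u: np.ndarray, spacing):
    """Pure and mixed second derivatives; returns (diag, mixed) dicts."""
    diag = {}
    for ax in range(3):
        h = spacing[ax]
        diag[ax] = (_shift(u, ax, +1) - 2.0 * u + _shift(u, ax, -1)) / (h * h)
    grads = central_gradients(u, spacing)
    mixed = {}
    for a in range(3):
        for b in range(a + 1, 3):
            mixed[(a, b)] = (
                _shift(grads[b], a, +1) - _shift(grads[b], a, -1)
            ) / (2.0 * spacing[a])
    return diag, mixed


def curvature_motion(u: np.ndarray, spacing, eps: float) -> np.ndarray:
    """Regularized ``kappa * |grad u|_eps`` (see module docstring)."""
    grads = central_gradients(u, spacing)
    diag, mixed = second_derivatives(u, spacing)
    q = eps * eps
    for g in grads:
        q = q + g * g
    num = np.zeros_like(u)
    for a in range(3):
        num += diag[a] * (q - grads[a] * grads[a])
    for (a, b), uab in mixed.items():
        num -= 2.0 * grads[a] * grads[b] * uab
    return num / q


def upwind_grad_mag(u: np.ndarray, spacing, speed_sign: int) -> np.ndarray:
    """Godunov gradient magnitude for ``u_t = c |grad u|`` with sign(c) given.

    ``speed_sign=-1`` (erosion, shrinking bright superlevel sets) and
    ``+1`` (dilation) select the monotone one-sided differences.
    """
    acc = np.zeros_like(u)
    for ax in range(3):
        dp = forward_diff(u, ax, spacing[ax])
        dm = backward_diff(u, ax, spacing[ax])
        if speed_sign < 0:
            acc += np.maximum(dm, 0.0) ** 2 + np.minimum(dp, 0.0) ** 2
        else:
            acc += np.maximum(dp, 0.0) ** 2 + np.minimum(dm, 0.0) ** 2
    return np.sqrt(acc)


def upwind_advection(u: np.ndarray, velocity: list[np.ndarray], spacing) -> np.ndarray:
    """Upwind evaluation of ``v . grad u`` for a frozen velocity field ``v``."""
    out = np.zeros_like(u)
    for ax in range(3):
        v = velocity[ax]
        dp = forward_diff(u, ax, spacing[ax])
        dm = backward_diff(u, ax, spacing[ax])
        # u_t = v u_x: characteristics run along -v, so positive v uses the
        # forward (downwind in -v) difference
        out += np.where(v > 0, v * dp, v * dm)
    return out


def presmoothed_gradient_mag(values: np.ndarray, spacing, sigma_um: float) -> np.ndarray:
    """|grad(G_sigma * u)| with sigma given in µm, converted per axis to voxels."""
    if sigma_um > 0:
        sig_vox = [sigma_um / h for h in spacing]
        sm = gaussian_filter(values, sigma=sig_vox, mode="nearest")
    else:
        sm = values
    grads = central_gradients(sm, spacing)
    return np.sqrt(sum(g * g for g in grads))


def stable_tau(spacing, diffusion_max: float, velocity_max: float = 0.0,
               safety: float = 0.4) -> float:
    """Explicit-scheme step bound: tau <= safety / (2 D sum 1/h^2 + sum |v|/h)."""
    diff = 2.0 * max(diffusion_max, 1e-300) * sum(1.0 / h**2 for h in spacing)
    adv = velocity_max * sum(1.0 / h for h in spacing)
    return safety / (diff + adv)


def check_stable(u: np.ndarray, lo: float, hi: float, stage: str, tau: float):
    """Raise when the explicit step went unstable.

    Instability shows up either as non-finite values or as a gross overshoot
    of the input range (caught before the min–max limiter would mask it).
    """
    bad = not np.all(np.isfinite(u))
    if not bad and hi > lo:
        overshoot = max(float(u.max()) - hi, lo - float(u.min()))
        bad = overshoot > 10.0 * (hi - lo)
    if bad:
        raise FloatingPointError(
            f"{stage}: PDE step diverged (tau={tau:g}); "
            "the explicit scheme went unstable — use a smaller tau"
        )
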