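"""GRASP compressed-sensing baseline for radial real-time cine.

Reconstructs a dynamic image series from undersampled multi-coil radial
k-space by minimizing

    f(x) = sum_f || F_f S x_f - y_f ||^2 + lambda * sum sqrt(|D_t x|^2 + eps)

where ``F_f`` is frame f's forward NUFFT, ``S`` multiplies by the coil
sensitivities, and ``D_t`` is the circular temporal first difference
(smoothed-l1 temporal total variation).  The regularization weight is
specified relative to the peak magnitude of the DCF-gridded initial image,
matching the convention of the original release of the framework.
Optimization is nonlinear conjugate gradient (Polak-Ribiere with restart)
with backtracking line search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from radcine.coils import coil_combine
from radcine.radial import RadialTrajectory, nufft_adjoint, nufft_forward


@dataclass
class GraspConfig:
    """Solver settings; defaults follow the published protocol.

    ``lambda_rel`` is the temporal-TV weight relative to the initial
    image's peak magnitude (0.02); ``max_line_search`` caps objective
    evaluations per outer iteration (150); 30 outer iterations total.
    """

    lambda_rel: float = 0.02
    n_iterations: int = 30
    max_line_search: int = 150
    tv_epsilon: float = 1e-15  # relative to (peak initial magnitude)^2
    numpoints: int = 4
    line_search_c1: float = 0.01
    backtrack_factor: float = 0.6

    def __post_init__(self) -> None:
        if self.lambda_rel < 0:
            raise ValueError("lambda_rel must be >= 0")
        if self.n_iterations < 1 or self.max_line_search < 1:
            raise ValueError("n_iterations and max_line_search must be >= 1")
        if self.tv_epsilon <= 0:
            raise ValueError("tv_epsilon must be > 0")


def _temporal_diff(x: np.ndarray) -> np.ndarray:
    # circular forward difference along the last (time) axis
    return np.roll(x, -1, axis=-1) - x


def _temporal_diff_adjoint(v: np.ndarray) -> np.ndarray:
    return np.roll(v, 1, axis=-1) - v


def grasp_objective(
    x: np.ndarray,
    y: np.ndarray,
    sens: np.ndarray,
    traj: RadialTrajectory,
    lam: float,
    eps: float,
    numpoints: int = 4,
    want_gradient: bool = True,
):
    """Objective value and (optionally) its gradient.

    Parameters
    ----------
    x : complex cine ``(n, n, n_t)``.
    y : radial samples ``(n_coils, n_t, spokes_per_frame, n_readout)``.
    sens : ``(n_coils, n, n)`` complex maps.
    lam, eps : absolute regularization weight and smoothing constant.

    Returns ``objective`` or ``(objective, gradient)``; the gradient is the
    Wirtinger-calculus descent direction ``2 d f / d conj(x)``, so the
    directional derivative of f along a complex step d is
    ``Re <gradient, d>``.
    """
    if x.shape[:2] != sens.shape[1:]:
        raise ValueError(f"image {x.shape} does not match sensitivities {sens.shape}")
    if y.shape[0] != sens.shape[0] or y.shape[1] != x.shape[-1]:
        raise ValueError(f"samples {y.shape} inconsistent with image/sens")
    sx = sens[:, :, :, None] * x[None]
    resid = nufft_forward(sx, traj, numpoints=numpoints) - y
    data_term = float(np.vdot(resid, resid).real)
    dt = _temporal_diff(x)
    root = np.sqrt(np.abs(dt) ** 2 + eps)
    tv_term = float(lam * root.sum())
    obj = data_term + tv_term
    if not want_gradient:
        return obj
    back = nufft_adjoint(resid, traj, x.shape[0], apply_dcf=False, numpoints=numpoints)
    grad = 2.0 * coil_combine(back, sens, normalize=False)
    grad += lam * _temporal_diff_adjoint(dt / root)
    return obj, grad


def grasp_reconstruct(
    y: np.ndarray,
    sens: np.ndarray,
    traj: RadialTrajectory,
    cfg: GraspConfig | None = None,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Temporal-TV-regularized reconstruction by nonlinear conjugate gradient.

    Initialized at the DCF-gridded coil-combined image (or ``x0``).  The
    backtracking line search accepts the first step satisfying the Armijo
    sufficient-decrease condition, trying at most ``cfg.max_line_search``
    candidates per iteration; if none qualifies the step is zero and the
    search direction restarts at steepest descent, so the objective trace is
    non-increasing by construction.

    Returns the reconstruction and the objective trace (initial value plus
    one entry per outer iteration).
    """
    if cfg is None:
        cfg = GraspConfig()
    n = sens.shape[1]
    if x0 is None:
        gridded = nufft_adjoint(
            y, traj, n, apply_dcf=True, numpoints=cfg.numpoints
        )
        x0 = coil_combine(gridded, sens)
    x = np.asarray(x0, dtype=np.complex128).copy()
    peak = float(np.abs(x).max())
    if peak == 0.0:
        peak = 1.0  # all-zero data: objective is pure data term
    lam = cfg.lambda_rel * peak
    eps = cfg.tv_epsilon * peak**2

    def fg(z, want_gradient=True):
        return grasp_objective(
            z, y, sens, traj, lam, eps, cfg.numpoints, want_gradient
        )

    obj, grad = fg(x)
    trace = [obj]
    direction = -grad
    step = 1.0
    for _ in range(cfg.n_iterations):
        slope = float(np.vdot(grad, direction).real)
        if slope >= 0:  # not a descent direction: restart on steepest descent
            direction = -grad
            slope = float(np.vdot(grad, direction).real)
        t = step
        accepted = False
        for _ in range(cfg.max_line_search):
            candidate = x + t * direction
            cand_obj = fg(candidate, want_gradient=False)
            if cand_obj <= obj + cfg.line_search_c1 * t * slope:
                accepted = True
                break
            t *= cfg.backtrack_factor
        if accepted:
            x = candidate
            new_obj, new_grad = fg(x)
            # Polak-Ribiere with nonnegativity restart
            beta = max(
                0.0,
                float(np.vdot(new_grad, new_grad - grad).real)
                / max(float(np.vdot(grad, grad).real), 1e-300),
            )
            direction = -new_grad + beta * direction
            grad = new_grad
            obj = new_obj
            step = min(t * 2.0, 1e6)  # warm-start the next search
        else:
            # zero step: keep x, restart direction (trace stays flat)
            direction = -grad
            step = 1.0
        trace.append(obj)
    return x, trace
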