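"""Levenberg-Marquardt: damped Gauss-Newton for nonlinear least squares.

Solves min_theta 0.5 * ||r(theta)||^2 given the residual function and its
Jacobian. Steps solve (J^T J + lambda I) d = -J^T r; the damping factor is
multiplied by 10 on a rejected step (SSE would increase) and divided by 10
on acceptance, so the recorded SSE path is monotone non-increasing by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["LMResult", "levenberg_marquardt"]


@dataclass
class LMResult:
    theta: np.ndarray
    sse: float
    n_iter: int
    converged: bool
    status: str
    sse_path: np.ndarray = field(repr=False)  # SSE after each accepted step


def levenberg_marquardt(
    residual: Callable[[np.ndarray], np.ndarray],
    jacobian: Callable[[np.ndarray], np.ndarray],
    theta0: np.ndarray,
    max_iter: int = 200,
    lam0: float = 1e-3,
    step_tol: float = 1e-10,
    grad_tol: float = 1e-8,
    lam_max: float = 1e12,
) -> LMResult:
    """Minimize 0.5*||residual(theta)||^2 from theta0.

    Termination: gradient infinity-norm below ``grad_tol``, accepted step
    shorter than ``step_tol`` (relative to ||theta||), damping exceeding
    ``lam_max`` (no downhill step exists numerically), or ``max_iter``
    accepted iterations.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    r = residual(theta)
    sse = float(r @ r)
    lam = lam0
    path = [sse]
    status, converged = "max_iter", False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        j = jacobian(theta)
        g = j.T @ r                      # gradient of 0.5*SSE
        if np.max(np.abs(g)) < grad_tol:
            status, converged = "gradient", True
            n_iter -= 1
            break
        jtj = j.T @ j
        eye = np.eye(jtj.shape[0])
        accepted = False
        while lam <= lam_max:
            try:
                step = np.linalg.solve(jtj + lam * eye, -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            r_new = residual(theta + step)
            sse_new = float(r_new @ r_new)
            if np.isfinite(sse_new) and sse_new < sse:
                theta = theta + step
                r, sse = r_new, sse_new
                lam = max(lam / 10.0, 1e-15)
                path.append(sse)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            status, converged = "stalled", True
            break
        if np.linalg.norm(step) < step_tol * (np.linalg.norm(theta) + step_tol):
            status, converged = "step", True
            break
    return LMResult(
        theta=theta,
        sse=sse,
        n_iter=n_iter,
        converged=converged,
        status=status,
        sse_path=np.asarray(path),
    )
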