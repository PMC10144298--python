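"""Scaled conjugate gradient (SCG) minimization.

Møller's SCG is a conjugate-direction optimizer that replaces the line
search with a one-dimensional second-order estimate obtained by a finite
difference of the gradient along the search direction, stabilized by
Levenberg-style damping. A step is accepted only when the comparison
ratio (predicted vs. actual decrease) indicates a genuine reduction, so
the tracked loss sequence is non-increasing by construction.

This is the optimizer used both for autoencoder reconstruction training
and for the softmax classifier's cross-entropy fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

_TINY = 1e-300
_LAMBDA_MAX = 1e20


@dataclass
class SCGResult:
    """Outcome of an SCG run.

    ``losses`` holds the objective at the start plus after every accepted
    step; it is non-increasing. ``reason`` is one of ``"tol"``,
    ``"gradient"``, ``"max_iter"``, ``"stalled"``.
    """

    w: np.ndarray
    losses: list[float] = field(default_factory=list)
    n_iter: int = 0
    reason: str = ""


def minimize_scg(fun_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
                 w0: np.ndarray,
                 max_iter: int = 1000,
                 tol: float = 1e-8,
                 sigma0: float = 1e-4,
                 lambda0: float = 1e-6,
                 tol_patience: int = 5) -> SCGResult:
    """Minimize ``fun_grad`` (returning loss and gradient) from ``w0``.

    Stops when the relative loss decrease stays below ``tol`` for
    ``tol_patience`` consecutive accepted steps, when the gradient
    vanishes, when ``max_iter`` iterations elapse, or when the damping
    parameter overflows (flat/degenerate objective).
    """
    w = np.asarray(w0, dtype=float).copy()
    n_params = w.size
    f, g = fun_grad(w)
    if not np.isfinite(f):
        raise FloatingPointError("non-finite loss at initial point")
    r = -g
    p = r.copy()
    lam, lam_bar = float(lambda0), 0.0
    success = True
    delta = 0.0
    losses = [float(f)]
    small_steps = 0
    reason = "max_iter"
    k = 0
    while k < max_iter:
        pnorm2 = float(p @ p)
        if pnorm2 <= _TINY:
            reason = "gradient"
            break
        if success:
            sigma = sigma0 / np.sqrt(pnorm2)
            _, g_sigma = fun_grad(w + sigma * p)
            s = (g_sigma - (-r)) / sigma  # Hessian-vector estimate H p
            delta = float(p @ s)
        # scale (Levenberg damping) and make the curvature positive
        delta += (lam - lam_bar) * pnorm2
        if delta <= 0:
            lam_bar = 2.0 * (lam - delta / pnorm2)
            delta = -delta + lam * pnorm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, g_new = fun_grad(w + alpha * p)
        if not np.isfinite(f_new):
            raise FloatingPointError(f"divergence: non-finite loss at iteration {k}")
        comparison = 2.0 * delta * (f - f_new) / (mu * mu) if mu != 0 else -1.0
        if comparison >= 0:  # successful reduction
            w = w + alpha * p
            f_prev, f = f, float(f_new)
            r_new = -g_new
            lam_bar = 0.0
            success = True
            if (k + 1) % n_params == 0:  # periodic restart along steepest descent
                p = r_new.copy()
            else:
                beta = float(r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            losses.append(f)
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-30)
            rel = (f_prev - f) / max(abs(f_prev), _TINY)
            small_steps = small_steps + 1 if rel < tol else 0
            if small_steps >= tol_patience:
                reason = "tol"
                k += 1
                break
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam += delta * (1.0 - comparison) / pnorm2
        if lam > _LAMBDA_MAX:
            reason = "stalled"
            break
        k += 1
    else:
        reason = "max_iter"
    if float(r @ r) <= _TINY:
        reason = "gradient"
    return SCGResult(w=w, losses=losses, n_iter=k, reason=reason)
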