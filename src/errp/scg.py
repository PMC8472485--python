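"""Scaled conjugate gradient minimization (Moller, 1993).

A Hessian-free conjugate-gradient method for smooth unconstrained
minimization.  Curvature along the search direction is estimated by a
finite difference of the gradient, and a Levenberg-Marquardt-style damping
term lambda is raised whenever the local quadratic model fails (non-positive
curvature or a poor comparison ratio) and lowered when the model is good.
A step is accepted only if it actually decreases the objective, so the loss
over accepted iterates is non-increasing.  No line search and no randomness:
the iterate sequence is a deterministic function of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["ScgOptions", "ScgRecord", "scg_minimize"]


@dataclass(frozen=True)
class ScgOptions:
    max_iterations: int = 200
    sigma0: float = 1e-5  # relative step for the finite-difference curvature probe
    lambda0: float = 1e-7  # initial damping
    tolerance: float = 1e-8  # stop when the gradient norm falls below this


@dataclass
class ScgRecord:
    """Loss at the start plus after every accepted step, and why we stopped."""

    losses: list[float] = field(default_factory=list)
    termination: str = "max_iterations"
    n_iterations: int = 0
    n_accepted: int = 0


def scg_minimize(
    objective: Callable[[np.ndarray], tuple[float, np.ndarray]],
    w0: np.ndarray,
    opts: ScgOptions | None = None,
) -> tuple[np.ndarray, ScgRecord]:
    """Minimize ``objective`` (returning (value, gradient)) from ``w0``.

    Returns the best iterate found and a training record.  Raises
    FloatingPointError if the objective or gradient turns non-finite.
    """
    opts = opts or ScgOptions()

    def call(w: np.ndarray) -> tuple[float, np.ndarray]:
        f, g = objective(w)
        if not np.isfinite(f) or not np.all(np.isfinite(g)):
            raise FloatingPointError("objective or gradient became non-finite during SCG")
        return float(f), np.asarray(g, dtype=float)

    w = np.asarray(w0, dtype=float).copy()
    n = w.size
    f, g = call(w)
    record = ScgRecord(losses=[f])
    r = -g
    p = r.copy()
    success = True
    lam = opts.lambda0
    lam_bar = 0.0
    delta = 1.0
    big = 1.0 / np.finfo(float).tiny

    for k in range(1, opts.max_iterations + 1):
        record.n_iterations = k
        r_norm = np.linalg.norm(r)
        if r_norm < opts.tolerance:
            record.termination = "gradient"
            break
        p_sq = float(p @ p)
        if p_sq == 0.0:
            record.termination = "gradient"
            break

        if success:
            # second-order information along p via a gradient difference
            sigma = opts.sigma0 / np.sqrt(p_sq)
            _, g_probe = call(w + sigma * p)
            s = (g_probe - g) / sigma
            delta = float(p @ s)

        # damp: delta <- delta + (lam - lam_bar) |p|^2, force positive curvature
        delta = delta + (lam - lam_bar) * p_sq
        if delta <= 0:
            lam_bar = 2.0 * (lam - delta / p_sq)
            delta = -delta + lam * p_sq
            lam = lam_bar

        mu = float(p @ r)
        alpha = mu / delta
        f_new, g_new = call(w + alpha * p)
        Delta = 2.0 * delta * (f - f_new) / (mu * mu) if mu != 0 else -1.0

        if Delta >= 0:  # successful step: the quadratic model predicted a decrease
            w = w + alpha * p
            f = f_new
            g = g_new
            r_new = -g
            lam_bar = 0.0
            success = True
            record.n_accepted += 1
            record.losses.append(f)
            if record.n_accepted % n == 0:  # restart with steepest descent
                p = r_new.copy()
            else:
                beta = float(r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            if Delta >= 0.75:
                lam = max(lam / 4.0, np.finfo(float).tiny)
        else:
            lam_bar = lam
            success = False
        if Delta < 0.25:
            lam = lam + delta * (1.0 - Delta) / p_sq
        if lam > big:
            record.termination = "stalled"
            break

    return w, record
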