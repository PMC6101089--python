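"""Nonmonotone spectral projected gradient (SPG) solver.

Minimizes a smooth convex function over a closed convex set given only the
objective, its gradient and the Euclidean projection onto the set. The
variant implemented is the classic SPG2 scheme: at each iterate the
Barzilai-Borwein spectral step is projected to produce a feasible direction
``d = P(x - alpha*g) - x``, and a nonmonotone backtracking line search along
``x + lam*d`` accepts the first point whose objective does not exceed the
maximum over the last ``memory`` objective values plus a small sufficient
decrease. Because every trial point is a convex combination of two feasible
points, all iterates are feasible.

The model-fitting entry point :func:`fit` wires the probit negative
log-likelihood and the nuclear-norm-ball projection into this solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data import ObservedMatrix
from .probit import ModelConfig, neg_gradient, neg_log_likelihood
from .projection import nuclear_norm, project_nuclear_ball

__all__ = ["SolverConfig", "SolveReport", "spg_minimize", "fit"]


@dataclass(frozen=True)
class SolverConfig:
    """SPG hyperparameters.

    max_iter
        Iteration cap (default 300).
    tol
        Stopping threshold on the unit-step projected-gradient residual
        ``||P(X - g(X)) - X||_F`` (default 1e-6).
    memory
        Length of the nonmonotone line-search history (default 10; 1 gives a
        monotone Armijo search).
    gamma
        Sufficient-decrease parameter in (0, 1) (default 1e-4).
    alpha_min, alpha_max
        Clamp bounds for the spectral step (defaults 1e-10, 1e10).
    """

    max_iter: int = 300
    tol: float = 1e-6
    memory: int = 10
    gamma: float = 1e-4
    alpha_min: float = 1e-10
    alpha_max: float = 1e10

    def __post_init__(self) -> None:
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if not (0 < self.alpha_min < self.alpha_max):
            raise ValueError("need 0 < alpha_min < alpha_max")
        if not (0 < self.gamma < 1):
            raise ValueError("gamma must be in (0, 1)")
        if self.memory < 1:
            raise ValueError("memory must be >= 1")


@dataclass
class StepRecord:
    """Per-iteration line-search diagnostics (for audits and tests)."""

    lam: float
    gtd: float
    f_reference: float
    f_accepted: float


@dataclass
class SolveReport:
    X_hat: np.ndarray
    objective_trace: list[float]
    n_iter: int
    converged: bool
    residual: float
    steps: list[StepRecord] = field(default_factory=list)
    solver_config: SolverConfig | None = None


def _pg_residual(X: np.ndarray, g: np.ndarray, project: Callable) -> float:
    return float(np.linalg.norm(project(X - g) - X))


def spg_minimize(
    objective: Callable[[np.ndarray], float],
    gradient: Callable[[np.ndarray], np.ndarray],
    project: Callable[[np.ndarray], np.ndarray],
    X0: np.ndarray,
    config: SolverConfig | None = None,
) -> SolveReport:
    """Minimize ``objective`` over the set implied by ``project``.

    ``X0`` must be feasible (already projected). Stops when the projected
    gradient residual drops below ``config.tol`` or after ``max_iter``
    iterations.
    """
    cfg = config or SolverConfig()
    X = np.array(X0, dtype=float, copy=True)
    f = objective(X)
    if not math.isfinite(f):
        raise ValueError(f"objective non-finite at the starting point: {f}")
    g = gradient(X)

    trace = [f]
    steps: list[StepRecord] = []
    history = [f]

    residual = _pg_residual(X, g, project)
    if residual <= cfg.tol or cfg.max_iter == 0:
        return SolveReport(X, trace, 0, residual <= cfg.tol, residual, steps, cfg)

    g_inf = float(np.max(np.abs(g)))
    alpha = 1.0 / g_inf if g_inf > 0 else cfg.alpha_max
    alpha = min(max(alpha, cfg.alpha_min), cfg.alpha_max)

    converged = False
    n_iter = 0
    for _ in range(cfg.max_iter):
        d = project(X - alpha * g) - X
        gtd = float(np.sum(g * d))
        f_ref = max(history[-cfg.memory:])

        lam = 1.0
        X_new = X + d
        f_new = objective(X_new)
        stalled = False
        while f_new > f_ref + cfg.gamma * lam * gtd:
            # safeguarded quadratic interpolation backtracking
            denom = 2.0 * (f_new - f - lam * gtd)
            lam_q = -(gtd * lam * lam) / denom if denom > 0 else 0.5 * lam
            lam = min(max(lam_q, 0.1 * lam), 0.9 * lam)
            if lam < 1e-16:
                stalled = True  # no acceptable step length; stop at X
                break
            X_new = X + lam * d
            f_new = objective(X_new)
        if stalled:
            break

        g_new = gradient(X_new)
        s = X_new - X
        y = g_new - g
        sy = float(np.sum(s * y))
        ss = float(np.sum(s * s))
        alpha = ss / sy if sy > 0 else cfg.alpha_max
        alpha = min(max(alpha, cfg.alpha_min), cfg.alpha_max)

        X, f, g = X_new, f_new, g_new
        n_iter += 1
        trace.append(f)
        history.append(f)
        steps.append(StepRecord(lam=lam, gtd=gtd, f_reference=f_ref, f_accepted=f))

        residual = _pg_residual(X, g, project)
        if residual <= cfg.tol:
            converged = True
            break

    return SolveReport(X, trace, n_iter, converged, residual, steps, cfg)


def fit(
    A: ObservedMatrix,
    model: ModelConfig,
    solver: SolverConfig | None = None,
    seed: int = 0,
) -> SolveReport:
    """Recover the latent score matrix for an observed binary matrix.

    Maximizes the probit log-likelihood over the nuclear-norm ball of radius
    ``tau = sqrt(r*p*q)`` by SPG on the negated likelihood, starting from the
    zero matrix (feasible for any tau > 0). Deterministic given identical
    inputs; ``seed`` is accepted for interface uniformity with stochastic
    fitters and recorded nowhere else.
    """
    del seed  # the optimization itself is deterministic
    tau = model.tau(A.p, A.q)
    feas_cap = tau * (1.0 + 1e-6)

    def project(X: np.ndarray) -> np.ndarray:
        Y = project_nuclear_ball(X, tau)
        assert nuclear_norm(Y) <= feas_cap, "projection returned an infeasible point"
        return Y

    return spg_minimize(
        objective=lambda X: neg_log_likelihood(X, A, model),
        gradient=lambda X: neg_gradient(X, A, model),
        project=project,
        X0=np.zeros(A.shape),
        config=solver,
    )
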