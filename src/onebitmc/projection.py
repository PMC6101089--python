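"""Euclidean projection onto the nuclear-norm ball {X : ||X||_* <= tau}.

The projection is singular-value soft-thresholding: write X = U diag(s) V^T,
shrink the singular values by the smallest level lambda >= 0 for which
sum_i max(s_i - lambda, 0) <= tau, and rebuild. lambda is found exactly by
sorted-prefix water-filling (the same closed form as projecting a vector onto
the simplex/l1-ball), not by iterative bisection, so there is no tolerance
knob.
"""

from __future__ import annotations

import numpy as np

__all__ = ["soft_threshold_level", "project_nuclear_ball", "nuclear_norm"]

# singular values below this are numerical rank noise and treated as zero
_SV_FLOOR = 1e-12


def nuclear_norm(X: np.ndarray) -> float:
    """Sum of singular values."""
    return float(np.linalg.svd(np.asarray(X, dtype=float), compute_uv=False).sum())


def soft_threshold_level(singular_values, tau: float) -> float:
    """Smallest lambda >= 0 with sum_i max(s_i - lambda, 0) <= tau.

    ``singular_values`` must be sorted nonincreasing and nonnegative.
    Returns 0 when the spectrum is already inside the ball. Closed form: with
    s sorted descending and k* the largest k such that
    (s_1 + ... + s_k - tau) / k < s_k, lambda = (prefix-sum(k*) - tau) / k*.
    """
    s = np.asarray(singular_values, dtype=float)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("singular values must be a nonempty 1-D sequence")
    if np.any(s < 0):
        raise ValueError("negative singular value")
    if np.any(np.diff(s) > 0):
        raise ValueError("singular values must be sorted nonincreasing")
    if not tau > 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if s.sum() <= tau:
        return 0.0
    cumsum = np.cumsum(s)
    k = np.arange(1, s.size + 1)
    candidates = (cumsum - tau) / k
    active = candidates < s
    k_star = int(np.nonzero(active)[0][-1])
    return float(candidates[k_star])


def project_nuclear_ball(X: np.ndarray, tau: float) -> np.ndarray:
    """Project X onto {Y : ||Y||_* <= tau} in Frobenius norm.

    Identity when X is already inside the ball; idempotent; non-expansive.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in matrix to project")
    if not tau > 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    s = np.where(s < _SV_FLOOR, 0.0, s)
    if s.sum() <= tau:
        return X.copy()
    lam = soft_threshold_level(s, tau)
    s_new = np.maximum(s - lam, 0.0)
    return (U * s_new) @ Vt
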