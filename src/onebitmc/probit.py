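"""Probit observation model for one-bit matrix completion.

The observed label of cell (i, j) is modelled as the sign of ``x_ij + z_ij``
with Gaussian noise ``z_ij ~ N(0, sigma^2)``, equivalently

    P(a_ij = +1) = Phi(x_ij / sigma),

with Phi the standard normal CDF. The log-likelihood of the latent matrix X
over the observed set Omega is

    F(X) = sum_{(i,j) in Omega} log Phi(a_ij * x_ij / sigma),

which is concave in X. The solver consumes the *negated* likelihood and its
gradient; the public functions here report the (non-positive) likelihood.

All CDF evaluations go through ``scipy.special.log_ndtr``/``ndtr`` so that
strongly negative margins (x/sigma < -8) do not underflow to -inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr

from .data import ObservedMatrix

__all__ = ["ModelConfig", "link", "log_likelihood", "gradient"]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelConfig:
    """Model hyperparameters: noise scale and target rank.

    sigma
        Standard deviation of the latent Gaussian noise; the link divides by
        sigma, so it is tuned directly as a standard deviation.
    r
        Expected rank of the latent matrix. The nuclear-norm radius used by
        the solver is tau = sqrt(r * p * q), which is how a rank budget is
        turned into a convex constraint.
    """

    sigma: float
    r: int

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (isinstance(self.r, (int, np.integer)) and self.r >= 1):
            raise ValueError(f"r must be a positive integer, got {self.r}")

    def tau(self, p: int, q: int) -> float:
        """Nuclear-norm ball radius sqrt(r*p*q) for a p x q problem."""
        if self.r > min(p, q):
            raise ValueError(f"r={self.r} exceeds min(p, q)={min(p, q)}")
        return math.sqrt(self.r * p * q)

    @staticmethod
    def from_ratio(sigma: float, ratio: float, p: int, q: int) -> "ModelConfig":
        """Build a config from a rank ratio of r_max = min(p, q)."""
        r = max(1, round(ratio * min(p, q)))
        return ModelConfig(sigma=sigma, r=r)


def link(x, sigma: float):
    """Probit link Phi(x / sigma); strictly increasing, link(-x) = 1 - link(x)."""
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return ndtr(np.asarray(x, dtype=float) / sigma)


def _check_inputs(X: np.ndarray, A: ObservedMatrix) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape != A.shape:
        raise ValueError(f"latent matrix shape {X.shape} != data shape {A.shape}")
    if A.m == 0:
        raise ValueError("empty observed set: nothing to fit")
    return X


def log_likelihood(X: np.ndarray, A: ObservedMatrix, config: ModelConfig) -> float:
    """Probit log-likelihood of X over the observed entries; always <= 0."""
    X = _check_inputs(X, A)
    rr, cc = A.omega_indices()
    t = A.values[rr, cc] * X[rr, cc] / config.sigma
    return float(np.sum(log_ndtr(t)))


def gradient(X: np.ndarray, A: ObservedMatrix, config: ModelConfig) -> np.ndarray:
    """Gradient of the log-likelihood w.r.t. X; zero off Omega.

    d/dx log Phi(a*x/s) = (a/s) * phi(x/s) / Phi(a*x/s), computed as
    exp(log phi - log Phi) to stay finite for large negative margins.
    """
    X = _check_inputs(X, A)
    rr, cc = A.omega_indices()
    a = A.values[rr, cc].astype(float)
    t = X[rr, cc] / config.sigma
    log_phi = -0.5 * t * t - _LOG_SQRT_2PI  # phi is even: phi(a*t) = phi(t)
    g = np.zeros_like(X)
    g[rr, cc] = (a / config.sigma) * np.exp(log_phi - log_ndtr(a * t))
    return g


def neg_log_likelihood(X: np.ndarray, A: ObservedMatrix, config: ModelConfig) -> float:
    """Minimization-form objective consumed by the solver."""
    return -log_likelihood(X, A, config)


def neg_gradient(X: np.ndarray, A: ObservedMatrix, config: ModelConfig) -> np.ndarray:
    return -gradient(X, A, config)
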