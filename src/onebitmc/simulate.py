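"""Synthetic binary association data with the model's assumed structure.

The generator draws a low-rank latent matrix X_true = L R^T, adds i.i.d.
Gaussian noise Z, thresholds at zero to produce +/-1 labels, and samples the
observed set Omega entrywise-independently — a binomial observation model in
which each cell is observed with probability m/(pq). Under this construction
the label probabilities satisfy P(a_ij = +1) = Phi(x_ij / noise_sigma),
exactly the probit link the fitter assumes, so recovery experiments on this
data probe the method under its own assumptions.

Note the scale non-identifiability of one-bit data: multiplying X_true and
the noise scale by the same constant leaves the label distribution unchanged,
so recovery is assessed by rank-invariant criteria (sign accuracy, AUC,
correlation), never by Frobenius error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .data import ObservedMatrix

__all__ = [
    "GeneratorConfig",
    "generate_latent",
    "sample_observations",
    "make_benchmark",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth generative parameters.

    p, q
        Matrix dimensions (e.g. microbes x diseases).
    true_rank
        Rank of the latent matrix; must not exceed min(p, q).
    latent_scale
        Entrywise standard deviation of X_true.
    noise_sigma
        Standard deviation of the additive Gaussian noise; the
        signal-to-noise ratio latent_scale/noise_sigma controls difficulty.
    m_target
        Expected |Omega|; each cell is observed with probability
        m_target/(p*q) independently.
    seed
        Seed for all randomness in the generator.
    """

    p: int
    q: int
    true_rank: int
    latent_scale: float = 1.0
    noise_sigma: float = 0.2
    m_target: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_rank > min(self.p, self.q):
            raise ValueError(
                f"true_rank={self.true_rank} exceeds min(p, q)={min(self.p, self.q)}"
            )
        if not self.latent_scale > 0 or not self.noise_sigma > 0:
            raise ValueError("latent_scale and noise_sigma must be > 0")
        m = self.m_target if self.m_target is not None else self.p * self.q
        if not (0 < m <= self.p * self.q):
            raise ValueError(f"m_target must be in (0, p*q], got {m}")

    @property
    def obs_prob(self) -> float:
        m = self.m_target if self.m_target is not None else self.p * self.q
        return m / (self.p * self.q)

    def to_dict(self) -> dict:
        return asdict(self)


def generate_latent(config: GeneratorConfig) -> np.ndarray:
    """Draw X_true = L R^T with i.i.d. standard-normal factors, scaled so the
    entrywise standard deviation equals ``latent_scale``."""
    rng = np.random.default_rng(config.seed)
    L = rng.standard_normal((config.p, config.true_rank))
    R = rng.standard_normal((config.q, config.true_rank))
    # entry variance of L R^T is true_rank for unit-normal factors
    return (L @ R.T) * (config.latent_scale / math.sqrt(config.true_rank))


def sample_observations(X_true: np.ndarray, config: GeneratorConfig) -> ObservedMatrix:
    """Threshold X_true + Z at zero and reveal each cell independently.

    Labels follow P(+1) = Phi(x / noise_sigma); |Omega| ~ Binomial(pq,
    m_target/pq). Uses a seed offset so labels are not correlated with the
    factor draw from :func:`generate_latent`.
    """
    X_true = np.asarray(X_true, dtype=float)
    p, q = X_true.shape
    rng = np.random.default_rng((config.seed, 1))
    Z = rng.normal(0.0, config.noise_sigma, size=(p, q))
    labels = np.where(X_true + Z >= 0, 1, -1).astype(np.int8)
    mask = rng.random((p, q)) < config.obs_prob
    values = np.where(mask, labels, 0).astype(np.int8)
    row_ids = [f"m{i + 1}" for i in range(p)]
    col_ids = [f"d{j + 1}" for j in range(q)]
    return ObservedMatrix(row_ids, col_ids, values, mask)


def make_benchmark(
    config: GeneratorConfig, test_fraction: float = 0.2
) -> tuple[ObservedMatrix, list[tuple[int, int, int]]]:
    """Split the observed set into disjoint train/test parts.

    Returns the training ObservedMatrix (test entries blinded) and the
    held-out list of (row, col, label) triples; both come from the same
    X_true, and |train Omega| + |test| = |Omega|.
    """
    if not 0 <= test_fraction < 1:
        raise ValueError(f"test_fraction must be in [0, 1), got {test_fraction}")
    X_true = generate_latent(config)
    full = sample_observations(X_true, config)
    rr, cc = full.omega_indices()
    rng = np.random.default_rng((config.seed, 2))
    order = rng.permutation(rr.size)
    n_test = int(round(test_fraction * rr.size))
    test_idx = order[:n_test]
    test_rows, test_cols = rr[test_idx], cc[test_idx]
    train = full.mask_entries(test_rows, test_cols)
    held_out = [
        (int(i), int(j), int(full.values[i, j]))
        for i, j in zip(test_rows.tolist(), test_cols.tolist())
    ]
    return train, held_out
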