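"""Truncated-SVD imputation baseline.

Fills the unknown cells of the +/-1 adjacency with a constant, takes the
rank-``rank`` truncated SVD, and uses the reconstruction as prediction
scores. This is the naive comparator against which likelihood-based
completion is measured: it ignores the binary observation process entirely.
"""

from __future__ import annotations

import numpy as np

from .data import ObservedMatrix

__all__ = ["svd_impute"]


def svd_impute(A: ObservedMatrix, rank: int, fill: float = 0.0) -> np.ndarray:
    """Rank-truncated SVD reconstruction of the filled adjacency.

    ``fill`` (default 0, the midpoint of the +/-1 labels) replaces unknown
    entries before the decomposition. Returns the dense score matrix
    U_r diag(s_r) V_r^T.
    """
    r_max = min(A.p, A.q)
    if not 1 <= rank <= r_max:
        raise ValueError(f"rank must be in [1, {r_max}], got {rank}")
    M = A.values.astype(float)
    M[~A.observed] = fill
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    return (U[:, :rank] * s[:rank]) @ Vt[:rank]
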