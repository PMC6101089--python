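"""Cross-validation drivers and ranking metrics.

Metrics are implemented standalone (midrank AUC, grouped-threshold average
precision) so the package has no hard dependency on an external metrics
library; tests cross-check them against brute-force oracles and
scikit-learn.

Two blinding schemes are provided:

* ``all_observed`` — classic k-fold over every observed entry; each fold's
  blinded entries are scored with their true +/-1 labels.
* ``positives_only`` — the link-prediction protocol used for sparse
  association databases that record only positives: each blinded positive is
  scored against the candidate set of all pairs never observed as positive,
  and folds are pooled into a single score/label vector for one ROC/PR
  curve. Per-fold metrics are also reported, since averaging performance
  over rounds is the other common convention.

Scores are the latent-matrix entries themselves; AUC is invariant under any
strictly monotone transform, so ranking by x_ij or by the link probability
Phi(x_ij/sigma) is equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import ObservedMatrix
from .probit import ModelConfig
from .spg import SolverConfig, fit

__all__ = [
    "CVConfig",
    "EvalResult",
    "FoldResult",
    "auc",
    "aupr",
    "roc_points",
    "pr_points",
    "make_folds",
    "run_cv",
    "grid_search",
    "GridSearchResult",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _validate_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    if not np.all(np.isin(labels, (1, -1))):
        raise ValueError("labels must be +1 or -1")
    return scores, labels.astype(int)


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equals P(score+ > score-) + 0.5 * P(tie), computed with midranks; this is
    exactly the trapezoidal area under the full ROC curve.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # midranks for ties
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _grouped_counts(scores: np.ndarray, labels: np.ndarray):
    """Cumulative TP/FP walking thresholds from high to low, ties grouped."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # last index of each tie group
    boundaries = np.nonzero(np.diff(s))[0]
    idx = np.r_[boundaries, s.size - 1]
    tp = np.cumsum(y == 1)[idx].astype(float)
    fp = np.cumsum(y == -1)[idx].astype(float)
    return tp, fp


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve, non-interpolated.

    Average precision: precision at each threshold weighted by the recall
    increment; tied scores collapse to a single threshold. The step-function
    sum is used rather than trapezoids, which are known to overestimate PR
    area.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("AUPR requires at least one positive")
    tp, fp = _grouped_counts(scores, labels)
    precision = tp / (tp + fp)
    recall = tp / n_pos
    d_recall = np.diff(np.r_[0.0, recall])
    return float(np.sum(precision * d_recall))


def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) point sequence from (0, 0) to (1, 1), ties grouped."""
    scores, labels = _validate_scores_labels(scores, labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    tp, fp = _grouped_counts(scores, labels)
    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, tp / n_pos]
    return fpr, tpr


def pr_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """(recall, precision) point sequence with nondecreasing recall."""
    scores, labels = _validate_scores_labels(scores, labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("PR curve requires at least one positive")
    tp, fp = _grouped_counts(scores, labels)
    recall = tp / n_pos
    precision = tp / (tp + fp)
    return recall, precision


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVConfig:
    """Cross-validation layout.

    scheme
        ``"loocv"`` (one blinded sample per fold) or ``"kfold"``.
    k
        Number of folds for k-fold (default 5); ignored for LOOCV.
    seed
        Seed for the random fold assignment.
    blind_set
        Which observed entries are blinded: ``"positives_only"`` (ranking
        protocol; default) or ``"all_observed"``.
    """

    scheme: str = "loocv"
    k: int = 5
    seed: int = 0
    blind_set: str = "positives_only"

    def __post_init__(self) -> None:
        if self.scheme not in ("loocv", "kfold"):
            raise ValueError(f"scheme must be loocv/kfold, got {self.scheme!r}")
        if self.scheme == "kfold" and self.k < 2:
            raise ValueError(f"k must be >= 2 for kfold, got {self.k}")
        if self.blind_set not in ("positives_only", "all_observed"):
            raise ValueError(f"unknown blind_set {self.blind_set!r}")


@dataclass
class FoldResult:
    scores: np.ndarray
    labels: np.ndarray
    auc: float | None
    aupr: float | None


@dataclass
class EvalResult:
    """Pooled scores/labels, curves and metrics, plus per-fold results."""

    scores: np.ndarray
    labels: np.ndarray
    roc: tuple[np.ndarray, np.ndarray]
    pr: tuple[np.ndarray, np.ndarray]
    auc: float
    aupr: float
    per_fold: list[FoldResult] = field(default_factory=list)

    @property
    def mean_fold_auc(self) -> float | None:
        vals = [f.auc for f in self.per_fold if f.auc is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def mean_fold_aupr(self) -> float | None:
        vals = [f.aupr for f in self.per_fold if f.aupr is not None]
        return float(np.mean(vals)) if vals else None

    def metrics_dict(self) -> dict:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "mean_fold_auc": self.mean_fold_auc,
            "mean_fold_aupr": self.mean_fold_aupr,
            "n_folds": len(self.per_fold),
            "n_evaluated_pairs": int(self.scores.size),
        }


def make_folds(A: ObservedMatrix, cv: CVConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition the blinded sample set into test folds.

    Every blinded sample lands in exactly one fold; k-fold sizes differ by at
    most one. Deterministic given (A, cv.seed).
    """
    if cv.blind_set == "positives_only":
        rr, cc = np.nonzero(A.observed & (A.values == 1))
    else:
        rr, cc = A.omega_indices()
    n = rr.size
    if n == 0:
        raise ValueError("no samples to blind")
    if cv.scheme == "loocv":
        return [(rr[i : i + 1], cc[i : i + 1]) for i in range(n)]
    if cv.k > n:
        raise ValueError(f"k={cv.k} exceeds number of blinded samples {n}")
    rng = np.random.default_rng(cv.seed)
    order = rng.permutation(n)
    return [(rr[chunk], cc[chunk]) for chunk in np.array_split(order, cv.k)]


def _default_scorer(model: ModelConfig, solver: SolverConfig | None) -> Callable:
    def scorer(A_train: ObservedMatrix) -> np.ndarray:
        return fit(A_train, model, solver).X_hat

    return scorer


def run_cv(
    A: ObservedMatrix,
    model: ModelConfig | None = None,
    solver: SolverConfig | None = None,
    cv: CVConfig = CVConfig(),
    scorer: Callable[[ObservedMatrix], np.ndarray] | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> EvalResult:
    """Cross-validate a matrix-completion scorer.

    For each fold the blinded entries are removed from Omega, the model is
    refit on the remainder (``scorer`` maps a training ObservedMatrix to a
    dense score matrix; defaults to the probit completion fit), and scores
    are collected for the blinded samples — plus, in ``positives_only``
    mode, for every pair never observed as positive. Results are pooled
    across folds into one score/label vector, and per-fold metrics are
    reported alongside.
    """
    if scorer is None:
        if model is None:
            raise ValueError("provide either a ModelConfig or an explicit scorer")
        scorer = _default_scorer(model, solver)
    if folds is None:
        folds = make_folds(A, cv)

    if cv.blind_set == "positives_only":
        neg_rows, neg_cols = np.nonzero(A.values != 1)  # unknown or observed -1
    else:
        neg_rows = neg_cols = None

    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    per_fold: list[FoldResult] = []
    for test_rows, test_cols in folds:
        A_train = A.mask_entries(test_rows, test_cols)
        if not np.any(A_train.values == 1):
            raise ValueError("fold leaves no training positives")
        X_hat = scorer(A_train)
        scores = X_hat[test_rows, test_cols].astype(float)
        labels = A.values[test_rows, test_cols].astype(int)
        if cv.blind_set == "positives_only":
            scores = np.r_[scores, X_hat[neg_rows, neg_cols]]
            labels = np.r_[labels, -np.ones(neg_rows.size, dtype=int)]
        fold_auc = fold_aupr = None
        if np.any(labels == 1):
            fold_aupr = aupr(scores, labels)
            if np.any(labels == -1):
                fold_auc = auc(scores, labels)
        per_fold.append(FoldResult(scores, labels, fold_auc, fold_aupr))
        all_scores.append(scores)
        all_labels.append(labels)

    pooled_scores = np.concatenate(all_scores)
    pooled_labels = np.concatenate(all_labels)
    return EvalResult(
        scores=pooled_scores,
        labels=pooled_labels,
        roc=roc_points(pooled_scores, pooled_labels),
        pr=pr_points(pooled_scores, pooled_labels),
        auc=auc(pooled_scores, pooled_labels),
        aupr=aupr(pooled_scores, pooled_labels),
        per_fold=per_fold,
    )


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

DEFAULT_SIGMAS = tuple(round(0.1 * i, 1) for i in range(1, 11))
DEFAULT_R_RATIOS = (1 / 10, 1 / 9, 1 / 8, 1 / 7, 1 / 6, 1 / 5, 1 / 4, 1 / 3, 1 / 2, 1.0)


@dataclass
class GridSearchResult:
    sigma: float
    r: int
    r_ratio: float
    aupr: float
    surface: pd.DataFrame  # rows = sigmas, columns = rank ratios


def grid_search(
    A: ObservedMatrix,
    sigmas=DEFAULT_SIGMAS,
    r_ratios=DEFAULT_R_RATIOS,
    solver: SolverConfig | None = None,
    cv: CVConfig = CVConfig(scheme="kfold", k=5),
    criterion: str = "aupr",
) -> GridSearchResult:
    """Tune (sigma, r) on a grid by cross-validated AUPR.

    Every cell is evaluated on the SAME folds (drawn once from ``cv.seed``)
    so fold noise cancels out of the comparison. The rank parameter is
    ``r = max(1, round(ratio * r_max))`` with ``r_max = min(p, q)``. AUPR is
    the selection criterion because the positives are vastly outnumbered.
    Ties are broken toward smaller r, then smaller sigma.
    """
    sigmas = list(sigmas)
    r_ratios = list(r_ratios)
    if not sigmas or not r_ratios:
        raise ValueError("sigma and rank-ratio lists must be nonempty")
    if criterion != "aupr":
        raise ValueError("only the AUPR criterion is supported")
    folds = make_folds(A, cv)
    r_max = min(A.p, A.q)

    surface = pd.DataFrame(index=sigmas, columns=r_ratios, dtype=float)
    surface.index.name = "sigma"
    surface.columns.name = "r_ratio"
    cache: dict[tuple[float, int], float] = {}
    cells = []
    for sigma in sigmas:
        for ratio in r_ratios:
            r = max(1, round(ratio * r_max))
            key = (sigma, r)
            if key not in cache:
                model = ModelConfig(sigma=sigma, r=r)
                cache[key] = run_cv(A, model, solver, cv, folds=folds).aupr
            surface.loc[sigma, ratio] = cache[key]
            cells.append((cache[key], r, sigma, ratio))

    best_aupr, best_r, best_sigma, best_ratio = min(
        cells, key=lambda c: (-c[0], c[1], c[2])
    )
    return GridSearchResult(
        sigma=best_sigma, r=best_r, r_ratio=best_ratio, aupr=best_aupr, surface=surface
    )
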