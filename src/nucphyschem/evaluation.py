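"""Stratified k-fold cross-validation and success-rate metrics.

Sensitivity Sn = (N+ - miss+)/N+ is the correct-prediction rate on
nucleosome-forming samples, specificity Sp = (N- - miss-)/N- the rate on
linker samples, and the overall success rate Acc pools the miss counts:
Acc = (N+ + N- - miss+ - miss-)/(N+ + N-).  Acc equals 1 exactly when no
sample of either class is mispredicted.  Errors are pooled over folds
(micro-average), which matches the global miss-count form of the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import cd_classifier
from .encoding import FeatureMatrix

__all__ = ["EvalResult", "stratified_folds", "cross_validate", "per_property_rates"]


@dataclass(frozen=True)
class EvalResult:
    """Pooled two-class success rates."""

    n_pos: int
    n_neg: int
    miss_pos: int
    miss_neg: int

    def __post_init__(self) -> None:
        if not (0 <= self.miss_pos <= self.n_pos and 0 <= self.miss_neg <= self.n_neg):
            raise ValueError("miss counts must lie within class sizes")

    @property
    def sn(self) -> float:
        return (self.n_pos - self.miss_pos) / self.n_pos

    @property
    def sp(self) -> float:
        return (self.n_neg - self.miss_neg) / self.n_neg

    @property
    def acc(self) -> float:
        total = self.n_pos + self.n_neg
        return (total - self.miss_pos - self.miss_neg) / total

    def to_dict(self) -> dict:
        return {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "miss_pos": self.miss_pos,
            "miss_neg": self.miss_neg,
            "sn": self.sn,
            "sp": self.sp,
            "acc": self.acc,
        }


def stratified_folds(y: Sequence[bool], k: int, seed: int) -> np.ndarray:
    """Assign each sample a fold id 0..k-1, stratified by class.

    Within each class, indices are shuffled with a seeded generator and
    dealt round-robin, so fold sizes per class differ by at most one.
    Deterministic for a given (labels, k, seed).
    """
    y = np.asarray(y, dtype=bool)
    if k < 2:
        raise ValueError("k must be >= 2")
    folds = np.empty(y.shape[0], dtype=np.int64)
    rng = np.random.default_rng(seed)
    for cls in (True, False):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(
                f"class {'positive' if cls else 'negative'} has {idx.size} samples, "
                f"fewer than k={k} folds"
            )
        perm = rng.permutation(idx)
        folds[perm] = np.arange(perm.size) % k
    return folds


def cross_validate(
    matrix: FeatureMatrix,
    feature_index: Optional[Sequence[int]] = None,
    k: int = 5,
    seed: int = 0,
    ridge: float = 0.0,
    folds: Optional[np.ndarray] = None,
) -> EvalResult:
    """k-fold CV of the covariant discriminant on a feature subset.

    For each fold: fit on the remaining folds, predict the held-out fold;
    miss counts are pooled over all folds.  Pass a precomputed ``folds``
    assignment to share one split across several calls (as the incremental
    feature selection sweep does).
    """
    if folds is None:
        folds = stratified_folds(matrix.y, k, seed)
    folds = np.asarray(folds)
    if feature_index is None:
        feature_index = np.arange(matrix.n_features)
    idx = np.asarray(feature_index, dtype=np.int64)

    miss_pos = miss_neg = 0
    for f in np.unique(folds):
        train = folds != f
        test = ~train
        sub = FeatureMatrix(
            X=matrix.X[train], y=matrix.y[train],
            ids=[matrix.ids[i] for i in np.flatnonzero(train)],
        )
        model = cd_classifier.fit(sub, feature_index=idx, ridge=ridge)
        pred, _ = cd_classifier.predict_batch(matrix.X[test][:, idx], model)
        truth = matrix.y[test]
        miss_pos += int(np.sum(truth & ~pred))
        miss_neg += int(np.sum(~truth & pred))
    return EvalResult(
        n_pos=matrix.n_pos, n_neg=matrix.n_neg, miss_pos=miss_pos, miss_neg=miss_neg
    )


def per_property_rates(
    matrix: FeatureMatrix,
    k: int = 5,
    seed: int = 0,
    ridge: float = 0.0,
) -> list[EvalResult]:
    """Cross-validate each contiguous per-property feature block separately.

    The concatenated encoding holds 12 equal blocks (one per property, 149
    features for 150-bp input); each block is evaluated as its own reduced
    working space, giving the per-property success-rate comparison.
    Returns 12 results in the frozen property order.
    """
    if matrix.n_features % 12 != 0:
        raise ValueError(
            f"feature count {matrix.n_features} is not 12 property blocks"
        )
    width = matrix.n_features // 12
    folds = stratified_folds(matrix.y, k, seed)
    results = []
    for b in range(12):
        idx = np.arange(b * width, (b + 1) * width)
        results.append(
            cross_validate(matrix, feature_index=idx, k=k, seed=seed,
                           ridge=ridge, folds=folds)
        )
    return results
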