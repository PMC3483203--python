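"""F-score feature ranking and incremental feature selection (IFS).

Each feature u gets the discrimination score

    F(u) = [(m+_u - m_u)^2 + (m-_u - m_u)^2] / (s2+_u + s2-_u)

where m_u is the overall mean, m+/m- the class means and s2+/s2- the
per-class sample variances (divisor n-1).  Larger means more
discriminative; the score is invariant to affine rescaling of the feature.

IFS walks the ranking from the top: for each subset size k the top-k
features form a nested candidate set S_k, evaluated by stratified k-fold
cross-validation of the covariant discriminant with ONE fold assignment
shared across every k so curve points are comparable; the optimal subset
is the smallest k attaining the maximal overall success rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .encoding import FeatureMatrix, feature_name
from .evaluation import EvalResult, cross_validate, stratified_folds

__all__ = [
    "FeatureRanking",
    "IFSCurve",
    "f_score",
    "f_scores",
    "rank_features",
    "ifs",
    "correlation_signs",
]


@dataclass(frozen=True)
class FeatureRanking:
    """Features sorted best-first with their parallel F-scores."""

    order: np.ndarray  # permutation of 0-based feature indices
    scores: np.ndarray  # non-increasing

    def __post_init__(self) -> None:
        if self.order.shape != self.scores.shape:
            raise ValueError("order and scores must be parallel")


@dataclass(frozen=True)
class IFSCurve:
    """Success rates along nested top-k feature subsets."""

    ks: np.ndarray
    results: tuple[EvalResult, ...]
    ranking: FeatureRanking

    @property
    def acc(self) -> np.ndarray:
        return np.asarray([r.acc for r in self.results])

    @property
    def optimal_k(self) -> int:
        """Smallest evaluated k attaining the maximum overall success rate."""
        acc = self.acc
        return int(self.ks[int(np.flatnonzero(acc == acc.max())[0])])

    @property
    def optimal_set(self) -> np.ndarray:
        """0-based indices of the optimal top-k features."""
        return self.ranking.order[: self.optimal_k]

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "k": self.ks,
                "sn": [r.sn for r in self.results],
                "sp": [r.sp for r in self.results],
                "acc": [r.acc for r in self.results],
            }
        ).to_csv(path, sep="\t", index=False)

    def write_optimal_set(self, path: str | Path, block_width: int = 149) -> None:
        """Write the optimal features as 1-based indices with decoding."""
        with open(path, "w") as fh:
            fh.write("feature_1based\tname\tf_score\n")
            for rank, idx in enumerate(self.optimal_set):
                fh.write(
                    f"{int(idx) + 1}\t{feature_name(int(idx), block_width)}"
                    f"\t{self.ranking.scores[rank]:.6g}\n"
                )


def f_scores(matrix: FeatureMatrix) -> np.ndarray:
    """Vectorized F-score of every feature column.

    Degenerate rule: when both within-class variances are zero the score is
    +inf if the class means differ and 0 if they are equal.
    """
    if matrix.n_pos < 2 or matrix.n_neg < 2:
        raise ValueError("each class needs >= 2 samples for variances")
    Xp, Xn = matrix.X[matrix.y], matrix.X[~matrix.y]
    m = matrix.X.mean(axis=0)
    mp, mn = Xp.mean(axis=0), Xn.mean(axis=0)
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = Xp.var(axis=0, ddof=1) + Xn.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = num / den
    zero_den = den == 0
    scores[zero_den & (mp != mn)] = np.inf
    scores[zero_den & (mp == mn)] = 0.0
    return scores


def f_score(matrix: FeatureMatrix, feature: int) -> float:
    """F-score of a single feature (0-based column index)."""
    return float(f_scores(matrix)[feature])


def rank_features(matrix: FeatureMatrix) -> FeatureRanking:
    """All features sorted by descending F-score, ties by ascending index."""
    scores = f_scores(matrix)
    order = np.argsort(-scores, kind="stable")
    return FeatureRanking(order=order, scores=scores[order])


def _k_schedule(n: int, stride: int, k_grid: Optional[Iterable[int]]) -> np.ndarray:
    if k_grid is not None:
        ks = np.unique(np.asarray(list(k_grid), dtype=np.int64))
        if ks.size == 0 or ks[0] < 1 or ks[-1] > n:
            raise ValueError(f"k_grid must contain values in 1..{n}")
        return ks
    if stride < 1:
        raise ValueError("stride must be >= 1")
    ks = np.arange(1, n + 1, stride, dtype=np.int64)
    if ks[-1] != n:
        ks = np.append(ks, n)
    return ks


def ifs(
    matrix: FeatureMatrix,
    ranking: Optional[FeatureRanking] = None,
    cv_folds: int = 5,
    seed: int = 0,
    stride: int = 1,
    k_grid: Optional[Iterable[int]] = None,
    ridge: float = 0.0,
) -> IFSCurve:
    """Incremental feature selection along an F-score ranking.

    Every evaluated subset is the top-k prefix of the ranking, so the
    subsets are nested by construction.  A single stratified fold
    assignment, drawn once from ``seed``, is reused for every k.  The full
    sweep (stride=1) evaluates all subset sizes; a coarser ``stride`` or an
    explicit ``k_grid`` trades resolution for runtime (the last point is
    always the full feature set when using a stride).
    """
    if ranking is None:
        ranking = rank_features(matrix)
    n = matrix.n_features
    if ranking.order.size != n:
        raise ValueError("ranking must cover all features")
    ks = _k_schedule(n, stride, k_grid)
    folds = stratified_folds(matrix.y, cv_folds, seed)
    results = []
    for k in ks:
        idx = ranking.order[:k]
        try:
            results.append(
                cross_validate(matrix, feature_index=idx, k=cv_folds,
                               seed=seed, ridge=ridge, folds=folds)
            )
        except Exception as exc:
            raise RuntimeError(f"IFS failed at subset size k={int(k)}") from exc
    return IFSCurve(ks=ks, results=tuple(results), ranking=ranking)


def correlation_signs(
    matrix: FeatureMatrix, feature_subset: Sequence[int]
) -> dict[int, str]:
    """Direction of each selected feature's association with the positive class.

    Sign of (mean over nucleosome rows - mean over linker rows) per
    feature: "positive", "negative", or "none" at exact equality.
    """
    idx = np.asarray(feature_subset, dtype=np.int64)
    if idx.size == 0:
        raise ValueError("feature subset must be non-empty")
    diff = matrix.X[matrix.y][:, idx].mean(axis=0) - matrix.X[~matrix.y][:, idx].mean(axis=0)
    out = {}
    for i, d in zip(idx, diff):
        out[int(i)] = "positive" if d > 0 else ("negative" if d < 0 else "none")
    return out
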