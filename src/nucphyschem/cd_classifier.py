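"""Covariant (quadratic) discriminant classifier.

Each class is summarized by its mean vector and covariance matrix; a query
vector x is scored against class g by

    F(x; g) = (x - mu_g)^T C_g^{-1} (x - mu_g) + ln|C_g|

i.e. the squared Mahalanobis distance to the class mean plus the
log-determinant of the class covariance, and assigned to the class with
the smaller score.  With equal class priors this is exactly quadratic
discriminant analysis; the benchmark classes are balanced, so no prior
term is used by default (an optional ln-prior addend is exposed).

Covariance matrices estimated from fewer samples than features, or from
collinear feature blocks, are singular; a small ridge (scaled to the mean
diagonal element) is added only when the Cholesky factorization fails, and
the constant actually applied is recorded on the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import scipy.linalg

from .encoding import LABEL_LINKER, LABEL_NUCLEOSOME, FeatureMatrix

__all__ = [
    "ClassModel",
    "CDModel",
    "Prediction",
    "fit",
    "mahalanobis_sq",
    "discriminant",
    "predict",
    "predict_batch",
    "save_model",
    "load_model",
]

_RIDGE_GROWTH = 10.0
_MAX_RIDGE_TRIES = 40


@dataclass
class ClassModel:
    """Gaussian summary of one class: mean, covariance, precision, ln|C|."""

    class_id: str
    mean: np.ndarray
    covariance: np.ndarray
    precision: np.ndarray
    log_det: float
    n_samples: int
    ridge_used: float

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


@dataclass
class CDModel:
    """Two-class covariant discriminant model.

    ``feature_index`` holds the 0-based indices of the original feature
    space this model operates on (the full range or a ranked subset); both
    class models share that dimension.
    """

    positive: ClassModel
    negative: ClassModel
    feature_index: np.ndarray
    log_prior_ratio: float = 0.0  # ln(pi+ / pi-); 0 for equal priors

    def __post_init__(self) -> None:
        self.feature_index = np.asarray(self.feature_index, dtype=np.int64)
        if self.positive.dim != self.negative.dim:
            raise ValueError("class models disagree on dimension")
        if self.feature_index.shape != (self.positive.dim,):
            raise ValueError("feature_index length must equal model dimension")

    @property
    def dim(self) -> int:
        return self.positive.dim


class Prediction(NamedTuple):
    label: str
    margin: float  # F(negative) - F(positive); >= 0 => nucleosome


def _fit_class(X: np.ndarray, class_id: str, ridge: float) -> ClassModel:
    n, d = X.shape
    if n < 2:
        raise ValueError(f"class {class_id!r}: need >= 2 samples, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"class {class_id!r}: non-finite feature values")
    mean = X.mean(axis=0)
    centered = X - mean
    cov = (centered.T @ centered) / (n - 1)  # unbiased, divisor N-1
    cov = (cov + cov.T) / 2.0
    if ridge > 0:
        cov = cov + ridge * np.eye(d)
    ridge_used = float(ridge)

    # ridge fallback: bump the diagonal until the matrix factorizes
    base = np.trace(cov) / d if np.trace(cov) > 0 else 1.0
    eps = 1e-6 * base
    reg = cov
    for _ in range(_MAX_RIDGE_TRIES):
        try:
            chol = scipy.linalg.cholesky(reg, lower=True)
            break
        except scipy.linalg.LinAlgError:
            reg = cov + eps * np.eye(d)
            ridge_used = float(ridge + eps)
            eps *= _RIDGE_GROWTH
    else:  # pragma: no cover - pathological input
        raise np.linalg.LinAlgError(
            f"class {class_id!r}: covariance not factorizable even after ridge"
        )
    log_det = 2.0 * float(np.sum(np.log(np.diag(chol))))
    ident = np.eye(d)
    precision = scipy.linalg.cho_solve((chol, True), ident)
    precision = (precision + precision.T) / 2.0
    return ClassModel(
        class_id=class_id,
        mean=mean,
        covariance=reg,
        precision=precision,
        log_det=log_det,
        n_samples=n,
        ridge_used=ridge_used,
    )


def fit(
    matrix: FeatureMatrix,
    feature_index: Optional[Sequence[int]] = None,
    ridge: float = 0.0,
    use_priors: bool = False,
) -> CDModel:
    """Fit per-class means and covariances on (a feature subset of) the data.

    Parameters
    ----------
    matrix : FeatureMatrix
        Labeled training samples; each class needs >= 2 rows.
    feature_index : sequence of int, optional
        0-based indices of the original features to model (default: all).
    ridge : float
        Constant added to every covariance diagonal up front.  Independent
        of this, a minimal automatic ridge is applied when factorization
        fails; the total is recorded per class as ``ridge_used``.
    use_priors : bool
        Add ln(n_class / n_total) class-prior terms to the discriminant.
        Off by default: the canonical training sets are balanced.
    """
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    if feature_index is None:
        feature_index = np.arange(matrix.n_features)
    idx = np.asarray(feature_index, dtype=np.int64)
    if idx.ndim != 1 or idx.size < 1:
        raise ValueError("feature_index must be a non-empty 1-D index list")
    Xp = matrix.X[matrix.y][:, idx]
    Xn = matrix.X[~matrix.y][:, idx]
    pos = _fit_class(Xp, LABEL_NUCLEOSOME, ridge)
    neg = _fit_class(Xn, LABEL_LINKER, ridge)
    log_prior_ratio = 0.0
    if use_priors:
        log_prior_ratio = float(np.log(pos.n_samples) - np.log(neg.n_samples))
    return CDModel(positive=pos, negative=neg, feature_index=idx,
                   log_prior_ratio=log_prior_ratio)


def mahalanobis_sq(x: np.ndarray, class_model: ClassModel) -> float:
    """Squared Mahalanobis distance (x - mu)^T C^{-1} (x - mu), >= 0."""
    x = np.asarray(x, dtype=float)
    if x.shape != (class_model.dim,):
        raise ValueError(
            f"dimension mismatch: x has shape {x.shape}, model dim {class_model.dim}"
        )
    d = x - class_model.mean
    return float(d @ class_model.precision @ d)


def discriminant(x: np.ndarray, class_model: ClassModel) -> float:
    """Class score: squared Mahalanobis distance + ln|C| (lower is closer)."""
    return mahalanobis_sq(x, class_model) + class_model.log_det


def predict(x: np.ndarray, model: CDModel) -> Prediction:
    """Assign x to the class with the smaller discriminant score.

    The margin is F(linker) - F(nucleosome); ties (margin exactly 0) go to
    the nucleosome class.  ``x`` is given in the model's feature subspace
    (already projected through ``feature_index``).
    """
    f_pos = discriminant(x, model.positive)
    f_neg = discriminant(x, model.negative)
    # optional prior enters as -2 ln(pi+/pi-) on the positive score
    if model.log_prior_ratio != 0.0:
        f_pos -= 2.0 * model.log_prior_ratio
    margin = f_neg - f_pos
    label = LABEL_NUCLEOSOME if margin >= 0 else LABEL_LINKER
    return Prediction(label=label, margin=float(margin))


def predict_batch(X: np.ndarray, model: CDModel) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized prediction over rows of X (already projected).

    Returns (labels, margins) where labels is boolean (True = nucleosome).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.dim:
        raise ValueError(
            f"dimension mismatch: X has shape {X.shape}, model dim {model.dim}"
        )
    scores = []
    for cm in (model.positive, model.negative):
        d = X - cm.mean
        msq = np.einsum("ij,jk,ik->i", d, cm.precision, d)
        scores.append(msq + cm.log_det)
    f_pos, f_neg = scores
    if model.log_prior_ratio != 0.0:
        f_pos = f_pos - 2.0 * model.log_prior_ratio
    margins = f_neg - f_pos
    return margins >= 0, margins


def project(X: np.ndarray, model: CDModel) -> np.ndarray:
    """Select the model's feature subset from full-width sample rows."""
    X = np.asarray(X, dtype=float)
    return X[:, model.feature_index] if X.ndim == 2 else X[model.feature_index]


def save_model(model: CDModel, path: str | Path, table_checksum: str = "") -> None:
    """Serialize a model to a NumPy .npz archive (documented layout).

    Keys: ``feature_index``, per-class ``{pos,neg}_mean`` /
    ``{pos,neg}_cov``, and a JSON ``meta`` string holding log-dets, sample
    counts, ridge constants, the prior term and the property-table
    checksum.  Precisions are re-derivable but stored for exact round-trip.
    """
    meta = {
        "format": "nucphyschem-cd-model/1",
        "pos": {
            "log_det": model.positive.log_det,
            "n_samples": model.positive.n_samples,
            "ridge_used": model.positive.ridge_used,
        },
        "neg": {
            "log_det": model.negative.log_det,
            "n_samples": model.negative.n_samples,
            "ridge_used": model.negative.ridge_used,
        },
        "log_prior_ratio": model.log_prior_ratio,
        "table_checksum": table_checksum,
    }
    np.savez(
        path,
        feature_index=model.feature_index,
        pos_mean=model.positive.mean,
        pos_cov=model.positive.covariance,
        pos_precision=model.positive.precision,
        neg_mean=model.negative.mean,
        neg_cov=model.negative.covariance,
        neg_precision=model.negative.precision,
        meta=np.array(json.dumps(meta)),
    )


def load_model(path: str | Path) -> CDModel:
    """Load a model serialized by :func:`save_model` (round-trip exact)."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta.get("format") != "nucphyschem-cd-model/1":
            raise ValueError(f"unrecognized model format in {path}")
        pos = ClassModel(
            class_id=LABEL_NUCLEOSOME,
            mean=z["pos_mean"],
            covariance=z["pos_cov"],
            precision=z["pos_precision"],
            log_det=float(meta["pos"]["log_det"]),
            n_samples=int(meta["pos"]["n_samples"]),
            ridge_used=float(meta["pos"]["ridge_used"]),
        )
        neg = ClassModel(
            class_id=LABEL_LINKER,
            mean=z["neg_mean"],
            covariance=z["neg_cov"],
            precision=z["neg_precision"],
            log_det=float(meta["neg"]["log_det"]),
            n_samples=int(meta["neg"]["n_samples"]),
            ridge_used=float(meta["neg"]["ridge_used"]),
        )
        return CDModel(
            positive=pos,
            negative=neg,
            feature_index=z["feature_index"],
            log_prior_ratio=float(meta.get("log_prior_ratio", 0.0)),
        )
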