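"""Quadratic discriminant classification and evaluation.

The classifier models each class k as a Gaussian N(mu_k, Sigma_k) with its
own covariance and assigns a point x to the class maximizing the
discriminant score

    delta_k(x) = -1/2 ln|Sigma_k| - 1/2 (x - mu_k)^T Sigma_k^{-1} (x - mu_k)
                 + ln(pi_k),

the log posterior up to a class-independent constant.  With a shared
covariance this degenerates to the linear discriminant, which is available
as ``model_type="lda"``.  Covariances get a small relative ridge
(reg * trace(Sigma)/p on the diagonal) so fits stay well-posed when a class
has fewer recordings than features.

Evaluation reports the confusion matrix (rows = true class) and the
one-vs-rest metrics ACC, TPR, FNR, PPV and FDR, with stratified k-fold
cross-validation and stratified hold-out protocols; ADASYN balancing can be
applied inside each training fold so synthetic points never leak into test
folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .audio_io import FeatureTable
from .balance import adasyn

__all__ = [
    "QDAModel",
    "ConfusionMatrix",
    "MetricsReport",
    "qda_fit",
    "qda_predict",
    "predict_batch",
    "confusion_from_predictions",
    "compute_metrics",
    "cross_validate",
    "holdout_validate",
]


@dataclass
class QDAModel:
    class_names: list[str]
    means: np.ndarray  # (K, p)
    covariances: np.ndarray  # (K, p, p)
    priors: np.ndarray  # (K,)
    regularization: float
    model_type: str = "qda"  # {"qda", "lda"}
    # cached Cholesky factors and log-determinants
    _chol: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _logdet: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self._chol is None:
            self._chol = np.linalg.cholesky(self.covariances)
            self._logdet = 2.0 * np.sum(
                np.log(np.diagonal(self._chol, axis1=1, axis2=2)), axis=1
            )

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def qda_fit(
    table: FeatureTable,
    reg: float = 1e-6,
    model_type: str = "qda",
) -> QDAModel:
    """Fit per-class means, covariances (n-1 denominator) and count priors.

    ``reg`` scales the ridge added to each covariance diagonal,
    reg * max(trace(Sigma)/p, eps); with ``model_type="lda"`` all classes
    share the pooled within-class covariance.
    """
    if model_type not in ("qda", "lda"):
        raise ValueError(f"unknown model type {model_type!r}")
    x, labels = table.matrix, table.labels
    classes = sorted(set(labels))
    p = x.shape[1]
    means, covs, priors = [], [], []
    for cls in classes:
        rows = x[labels == cls]
        if rows.shape[0] < 2:
            raise ValueError(f"class {cls!r} has {rows.shape[0]} rows; need >= 2 to fit")
        means.append(rows.mean(axis=0))
        covs.append(np.cov(rows, rowvar=False).reshape(p, p))
        priors.append(rows.shape[0] / x.shape[0])
    means = np.array(means)
    covs = np.array(covs)
    priors = np.array(priors)
    if model_type == "lda":
        weights = np.array([np.sum(labels == c) - 1 for c in classes], dtype=float)
        pooled = np.einsum("k,kij->ij", weights, covs) / weights.sum()
        covs = np.broadcast_to(pooled, covs.shape).copy()
    for k in range(len(classes)):
        ridge = reg * max(np.trace(covs[k]) / p, 1e-300)
        covs[k] = covs[k] + ridge * np.eye(p)
    return QDAModel([str(c) for c in classes], means, covs, priors, reg, model_type)


def _scores(model: QDAModel, x: np.ndarray) -> np.ndarray:
    """Discriminant scores delta_k for a batch, shape (n, K)."""
    n = x.shape[0]
    k = len(model.class_names)
    out = np.empty((n, k))
    for j in range(k):
        diff = x - model.means[j]
        sol = np.linalg.solve(model._chol[j], diff.T)  # lower-triangular solve
        maha = np.sum(sol * sol, axis=0)
        out[:, j] = -0.5 * model._logdet[j] - 0.5 * maha + np.log(model.priors[j])
    return out


def qda_predict(model: QDAModel, x: Sequence[float] | np.ndarray) -> tuple[str, np.ndarray]:
    """Predicted class and the per-class discriminant scores for one point.

    Ties go to the first class in the model's (sorted) class order.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {x.size}")
    scores = _scores(model, x[None, :])[0]
    return model.class_names[int(np.argmax(scores))], scores


def predict_batch(model: QDAModel, x: np.ndarray) -> np.ndarray:
    """Predicted class labels for a (n, p) matrix."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {x.shape[1]}")
    idx = np.argmax(_scores(model, x), axis=1)
    return np.array([model.class_names[i] for i in idx], dtype=object)


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K matching class_names")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.class_names != other.class_names:
            raise ValueError("class orders differ")
        return ConfusionMatrix(self.counts + other.counts, self.class_names)


def confusion_from_predictions(
    true: np.ndarray, predicted: np.ndarray, class_names: Sequence[str]
) -> ConfusionMatrix:
    names = list(class_names)
    index = {c: i for i, c in enumerate(names)}
    counts = np.zeros((len(names), len(names)), dtype=np.int64)
    for t, p in zip(true, predicted):
        counts[index[str(t)], index[str(p)]] += 1
    return ConfusionMatrix(counts, names)


@dataclass
class MetricsReport:
    accuracy: float
    tpr: dict[str, Optional[float]]
    fnr: dict[str, Optional[float]]
    ppv: dict[str, Optional[float]]
    fdr: dict[str, Optional[float]]
    confusion: ConfusionMatrix

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {
                c: {
                    "TPR": self.tpr[c],
                    "FNR": self.fnr[c],
                    "PPV": self.ppv[c],
                    "FDR": self.fdr[c],
                }
                for c in self.confusion.class_names
            },
            "confusion": self.confusion.counts.tolist(),
            "classes": self.confusion.class_names,
        }


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest TPR/FNR/PPV/FDR per class plus overall diagonal accuracy.

    A class with no true instances gets TPR/FNR = None (undefined, reported
    missing rather than zero); likewise PPV/FDR when nothing was predicted
    as that class.
    """
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(counts) / total)
    tpr: dict[str, Optional[float]] = {}
    fnr: dict[str, Optional[float]] = {}
    ppv: dict[str, Optional[float]] = {}
    fdr: dict[str, Optional[float]] = {}
    for i, cls in enumerate(cm.class_names):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tpr[cls] = float(tp / (tp + fn)) if tp + fn > 0 else None
        fnr[cls] = float(fn / (fn + tp)) if tp + fn > 0 else None
        ppv[cls] = float(tp / (tp + fp)) if tp + fp > 0 else None
        fdr[cls] = 1.0 - ppv[cls] if ppv[cls] is not None else None
    return MetricsReport(accuracy, tpr, fnr, ppv, fdr, cm)


def cross_validate(
    table: FeatureTable,
    folds: int = 5,
    seed: int = 0,
    balance_in_fold: bool = False,
    k_neighbors: int = 5,
    reg: float = 1e-6,
    model_type: str = "qda",
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Stratified k-fold evaluation with a pooled confusion matrix.

    With ``balance_in_fold``, ADASYN runs on each training part only, so
    synthetic interpolants never appear in a test fold.
    """
    labels = table.labels
    classes, counts = np.unique(labels, return_counts=True)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if counts.min() < folds:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small!r} has fewer members than folds={folds}")
    names = [str(c) for c in sorted(set(labels))]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y = np.array([str(c) for c in labels])
    per_fold: list[MetricsReport] = []
    pooled = ConfusionMatrix(np.zeros((len(names), len(names)), dtype=np.int64), names)
    for fold_i, (train_idx, test_idx) in enumerate(skf.split(table.matrix, y)):
        train = FeatureTable(
            table.matrix[train_idx],
            labels[train_idx],
            table.feature_names,
            table.provenance[train_idx],
        )
        if balance_in_fold:
            train = adasyn(train, k_neighbors=k_neighbors, seed=seed + fold_i)
        model = qda_fit(train, reg=reg, model_type=model_type)
        pred = predict_batch(model, table.matrix[test_idx])
        cm = confusion_from_predictions(labels[test_idx], pred, names)
        per_fold.append(compute_metrics(cm))
        pooled = pooled + cm
    return compute_metrics(pooled), per_fold


def holdout_validate(
    table: FeatureTable,
    test_fraction: float = 0.20,
    seed: int = 0,
    balance_train: bool = False,
    k_neighbors: int = 5,
    reg: float = 1e-6,
    model_type: str = "qda",
) -> MetricsReport:
    """Stratified train/test split evaluation (default 80/20)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    y = np.array([str(c) for c in table.labels])
    idx = np.arange(table.n_rows)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=y
    )
    names = sorted(set(y))
    for part, part_name in ((train_idx, "training"), (test_idx, "test")):
        present = set(y[part])
        if present != set(names):
            raise ValueError(f"class missing from the {part_name} split")
    train = FeatureTable(
        table.matrix[train_idx],
        table.labels[train_idx],
        table.feature_names,
        table.provenance[train_idx],
    )
    if balance_train:
        train = adasyn(train, k_neighbors=k_neighbors, seed=seed)
    model = qda_fit(train, reg=reg, model_type=model_type)
    pred = predict_batch(model, table.matrix[test_idx])
    cm = confusion_from_predictions(table.labels[test_idx], pred, names)
    return compute_metrics(cm)
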