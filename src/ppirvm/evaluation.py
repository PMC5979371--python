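"""Stratified five-fold cross-validation, confusion metrics and ROC.

Model quality is assessed by stratified k-fold cross-validation (default
k=5): the labeled pairs are split into k folds preserving the
interacting/non-interacting balance, each fold serves once as the test set,
and seven confusion-matrix metrics (accuracy, sensitivity, specificity,
positive/negative predictive value, F-score, Matthews correlation
coefficient) plus the ROC curve and its area are reported per fold and as
mean +/- sample standard deviation.  PCA and the RVM are fitted on training
folds only, so no information leaks from a test fold into its model.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold as _SkStratifiedKFold

from . import pca as _pca
from . import rvm as _rvm
from .lra import PairFeature, pair_matrix

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "FoldResult",
    "CVReport",
    "stratified_kfold",
    "compute_metrics",
    "roc_auc",
    "cross_validate",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f_score", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f_score: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _ratio(num: float, den: float, name: str) -> float:
    """Guarded ratio: a zero denominator yields 0 with a warning (the
    degenerate confusion-table case is otherwise undefined)."""
    if den == 0:
        logger.warning("%s has zero denominator; reporting 0", name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """The seven confusion-matrix metrics.

    accuracy   = (TP+TN) / (TP+FP+TN+FN)
    sensitivity= TP / (TP+FN)          specificity = TN / (TN+FP)
    PPV        = TP / (TP+FP)          NPV         = TN / (TN+FN)
    F-score    = 2*Sen*PPV / (Sen+PPV)
    MCC        = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        raise ValueError("empty confusion table")
    sen = _ratio(tp, tp + fn, "sensitivity")
    ppv = _ratio(tp, tp + fp, "ppv")
    mcc_den = math.sqrt(float(tp + fn) * (tn + fp) * (tp + fp) * (tn + fn))
    return MetricSet(
        accuracy=(tp + tn) / counts.total,
        sensitivity=sen,
        specificity=_ratio(tn, tn + fp, "specificity"),
        ppv=ppv,
        npv=_ratio(tn, tn + fn, "npv"),
        f_score=_ratio(2.0 * sen * ppv, sen + ppv, "f_score"),
        mcc=_ratio(tp * tn - fp * fn, mcc_den, "mcc"),
    )


def stratified_kfold(labels: Sequence[int], k: int = 5, seed: int = 0) -> np.ndarray:
    """Assign each sample to one of k folds, stratified by class.

    Per-class fold sizes differ by at most one; the shuffled assignment is
    reproducible under ``seed``.  Returns an array of fold indices in [0, k).
    """
    y = np.asarray(labels, dtype=int)
    n = y.size
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples n={n}")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present for stratification")
    splitter = _SkStratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), y)):
        assignment[test_idx] = fold
    return assignment


def roc_auc(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (fpr, tpr) over the unique-score threshold sweep, and the
    trapezoid area under the curve.  Tied scores share a threshold."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


# ---------------------------------------------------------------------------
# Cross-validation driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldResult:
    fold: int
    counts: ConfusionCounts
    metrics: MetricSet
    roc_points: list[tuple[float, float]]
    auc: float
    n_test: int
    n_relevance_vectors: int
    pca_k: int


@dataclass(frozen=True)
class CVReport:
    fold_results: list[FoldResult]
    fold_models: Optional[list[tuple[_pca.PCAModel, _rvm.RVMModel]]]
    mean: MetricSet
    std: MetricSet
    pooled_roc: list[tuple[float, float]]
    pooled_auc: float
    mean_auc: float
    k: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "folds": [
                {
                    "fold": f.fold,
                    "counts": asdict(f.counts),
                    "metrics": f.metrics.as_dict(),
                    "auc": f.auc,
                    "n_test": f.n_test,
                    "n_relevance_vectors": f.n_relevance_vectors,
                    "pca_k": f.pca_k,
                }
                for f in self.fold_results
            ],
            "mean": self.mean.as_dict(),
            "std": self.std.as_dict(),
            "mean_auc": self.mean_auc,
            "pooled_auc": self.pooled_auc,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _aggregate(metric_sets: Sequence[MetricSet]) -> tuple[MetricSet, MetricSet]:
    values = {name: np.array([getattr(m, name) for m in metric_sets]) for name in METRIC_NAMES}
    mean = MetricSet(**{k: float(np.mean(v)) for k, v in values.items()})
    # sample standard deviation over folds
    std = MetricSet(**{k: float(np.std(v, ddof=1)) for k, v in values.items()})
    return mean, std


def cross_validate(
    pairs: Sequence[PairFeature],
    pca_config: Optional[_pca.PCAConfig] = None,
    rvm_config: Optional[_rvm.RVMConfig] = None,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
    fold_assignment: Optional[np.ndarray] = None,
    keep_fold_models: bool = False,
) -> CVReport:
    """Stratified k-fold cross-validation of the PCA + RVM classifier.

    Per fold: PCA is fitted on the training rows only, both partitions are
    projected, the RVM classifier is fitted on the training fold and its
    probabilities on the test fold are thresholded at 0.5.

    ``fold_assignment`` overrides the internal stratified split (e.g. for
    grouped folding); ``keep_fold_models`` retains each fold's fitted
    (PCAModel, RVMModel) on the report for inspection.
    """
    pca_config = pca_config or _pca.PCAConfig()
    rvm_config = rvm_config or _rvm.RVMConfig()
    X, y = pair_matrix(pairs)
    if np.any(y < 0):
        raise ValueError("cross_validate requires every pair to be labeled")
    if fold_assignment is None:
        assignment = stratified_kfold(y, k=k, seed=seed)
    else:
        assignment = np.asarray(fold_assignment, dtype=int)
        if assignment.shape != y.shape or not np.array_equal(
            np.unique(assignment), np.arange(k)
        ):
            raise ValueError("fold_assignment must map every sample to a fold in [0, k)")

    fold_models: list[tuple[_pca.PCAModel, _rvm.RVMModel]] = []
    fold_results: list[FoldResult] = []
    pooled_scores = np.empty(y.size)
    for fold in range(k):
        test_mask = assignment == fold
        train_mask = ~test_mask
        for cls in (0, 1):
            if np.sum(y[train_mask] == cls) < 2 or np.sum(y[test_mask] == cls) < 1:
                raise ValueError(
                    f"fold {fold}: too few class-{cls} samples for a meaningful split"
                )
        try:
            model_pca = _pca.fit_pca(
                X[train_mask],
                variance_target=pca_config.variance_target,
                n_components=pca_config.n_components,
            )
            Z_train = _pca.apply_pca(model_pca, X[train_mask])
            Z_test = _pca.apply_pca(model_pca, X[test_mask])
            model, _diag = _rvm.fit_rvm_classifier(
                Z_train,
                y[train_mask],
                kernel=rvm_config.kernel,
                max_iter=rvm_config.max_iter,
                tol=rvm_config.tol,
                prune_threshold=rvm_config.prune_threshold,
            )
            scores = _rvm.predict(model, Z_test)
        except Exception as exc:
            raise RuntimeError(f"cross-validation failed in fold {fold}: {exc}") from exc
        if keep_fold_models:
            fold_models.append((model_pca, model))
        pooled_scores[test_mask] = scores
        pred = (scores >= threshold).astype(int)
        yt = y[test_mask]
        counts = ConfusionCounts(
            tp=int(np.sum((pred == 1) & (yt == 1))),
            fp=int(np.sum((pred == 1) & (yt == 0))),
            tn=int(np.sum((pred == 0) & (yt == 0))),
            fn=int(np.sum((pred == 0) & (yt == 1))),
        )
        points, auc = roc_auc(yt, scores)
        fold_results.append(
            FoldResult(
                fold=fold,
                counts=counts,
                metrics=compute_metrics(counts),
                roc_points=points,
                auc=auc,
                n_test=int(np.sum(test_mask)),
                n_relevance_vectors=model.n_relevance_vectors,
                pca_k=model_pca.k,
            )
        )

    mean, std = _aggregate([f.metrics for f in fold_results])
    pooled_points, pooled_auc = roc_auc(y, pooled_scores)
    return CVReport(
        fold_results=fold_results,
        fold_models=fold_models if keep_fold_models else None,
        mean=mean,
        std=std,
        pooled_roc=pooled_points,
        pooled_auc=pooled_auc,
        mean_auc=float(np.mean([f.auc for f in fold_results])),
        k=k,
        seed=seed,
    )
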