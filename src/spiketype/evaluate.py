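"""Separability, cross-validated performance, and classifier comparison.

* **J3 scatter criterion** — ``J3 = trace(Sb + Sw) / trace(Sw)`` with the
  class-size-weighted between-class scatter
  ``Sb = Σ_i n_i (m_i − m)(m_i − m)ᵀ`` and within-class scatter
  ``Sw = Σ_i Σ_j (x_ij − m_i)(x_ij − m_i)ᵀ``. Larger J3, better class
  separability; equal class means give exactly 1.
* **Per-class metrics** — one-vs-rest precision, recall, and accuracy from
  a confusion matrix; overall values are unweighted means over classes.
* **Cross-validation** — seeded, class-stratified spike-level k-fold.
  Standardization, PCA and FCM are refit per fold on the training parts
  only (a ``pca_global`` switch reproduces the laxer single-fit variant; a
  ``group_by_neuron`` switch keeps each neuron's spikes in one fold).
* **Classifier comparison** — Cochran's Q over ≥3 classifiers, the
  continuity-corrected McNemar test for pairs, Bonferroni adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from statsmodels.stats.contingency_tables import cochrans_q as _sm_cochrans_q
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .classify import classify, train
from .errors import ParameterError
from .features import FeatureMatrix, fit_pca


@dataclass
class ConfusionMatrix:
    """C×C counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_order: List[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        C = len(self.class_order)
        if self.counts.shape != (C, C):
            raise ParameterError("confusion matrix shape must match class_order")
        if (self.counts < 0).any():
            raise ParameterError("confusion counts must be non-negative")

    @staticmethod
    def from_labels(
        true: Sequence[str], pred: Sequence[str], class_order: Sequence[str]
    ) -> "ConfusionMatrix":
        order = list(class_order)
        index = {lab: i for i, lab in enumerate(order)}
        counts = np.zeros((len(order), len(order)), dtype=int)
        for t, p in zip(true, pred):
            counts[index[t], index[p]] += 1
        return ConfusionMatrix(counts=counts, class_order=order)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ScatterSummary:
    """J3 class-separability summary."""

    j3: float
    sw_trace: float
    sb_trace: float
    class_means: Dict[str, np.ndarray]
    grand_mean: np.ndarray
    class_sizes: Dict[str, int]


@dataclass
class EvaluationReport:
    """Cross-validation outcome: per-fold confusions plus fold-averaged metrics."""

    per_fold: List[ConfusionMatrix]
    per_class: Dict[str, Dict[str, Tuple[float, float]]]  # metric -> (mean, sem)
    overall: Dict[str, Tuple[float, float]]
    config: Dict
    seed: Optional[int]
    correct: np.ndarray  # per-spike correctness, original row order
    class_order: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict:
        return {
            "class_order": self.class_order,
            "per_fold_counts": [cm.counts.tolist() for cm in self.per_fold],
            "per_class": {
                cls: {metric: list(ms) for metric, ms in d.items()}
                for cls, d in self.per_class.items()
            },
            "overall": {metric: list(ms) for metric, ms in self.overall.items()},
            "config": self.config,
            "seed": self.seed,
        }


def j3_index(features: FeatureMatrix) -> ScatterSummary:
    """Scatter-matrix separability of labeled features."""
    if features.labels is None:
        raise ParameterError("j3_index requires labeled features")
    labels = np.asarray(features.labels)
    classes = sorted(set(features.labels))
    if len(classes) < 2:
        raise ParameterError("j3_index needs at least 2 classes")
    X = features.values
    m = X.mean(axis=0)
    sw = 0.0
    sb = 0.0
    class_means: Dict[str, np.ndarray] = {}
    class_sizes: Dict[str, int] = {}
    for cls in classes:
        Xi = X[labels == cls]
        mi = Xi.mean(axis=0)
        class_means[cls] = mi
        class_sizes[cls] = Xi.shape[0]
        sw += float(np.sum((Xi - mi) ** 2))
        sb += Xi.shape[0] * float(np.sum((mi - m) ** 2))
    if sw <= 0:
        raise ParameterError("zero within-class scatter; J3 undefined")
    return ScatterSummary(
        j3=(sb + sw) / sw,
        sw_trace=sw,
        sb_trace=sb,
        class_means=class_means,
        grand_mean=m,
        class_sizes=class_sizes,
    )


def class_metrics(cm: ConfusionMatrix) -> Dict:
    """One-vs-rest precision/recall/accuracy per class plus macro averages.

    A class never predicted (TP+FP = 0) has undefined precision; it is
    reported as ``None`` and excluded from the macro mean with a warning.
    """
    total = cm.total
    if total == 0:
        raise ParameterError("empty confusion matrix")
    counts = cm.counts
    per_class: Dict[str, Dict[str, Optional[float]]] = {}
    for i, cls in enumerate(cm.class_order):
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp
        tn = total - tp - fp - fn
        if tp + fp == 0:
            warnings.warn(
                f"class {cls!r} never predicted; precision undefined", stacklevel=2
            )
            precision = None
        else:
            precision = tp / (tp + fp)
        recall = tp / (tp + fn) if tp + fn > 0 else None
        per_class[cls] = {
            "precision": precision,
            "recall": recall,
            "accuracy": (tp + tn) / total,
        }
    overall = {}
    for metric in ("precision", "recall", "accuracy"):
        vals = [d[metric] for d in per_class.values() if d[metric] is not None]
        overall[metric] = float(np.mean(vals)) if vals else None
    return {"per_class": per_class, "overall": overall}


def _mean_sem(values: Sequence[float]) -> Tuple[float, float]:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    sem = float(np.std(arr, ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(arr.mean()), sem


def cross_validate(
    features: FeatureMatrix,
    k: int = 10,
    clusters_per_class: int = 2,
    pca_cpv: float = 0.90,
    n_components_override: Optional[int] = None,
    fcm_m: float = 2.0,
    fcm_tol: float = 1e-5,
    fcm_max_iter: int = 300,
    seed: Optional[int] = None,
    group_by_neuron: bool = False,
    pca_global: bool = False,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the center-repository classifier."""
    if features.labels is None:
        raise ParameterError("cross_validate requires labeled features")
    labels = np.asarray(features.labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise ParameterError(
            f"classes {list(small)} have fewer than k={k} spikes"
        )
    class_order = sorted(classes.tolist())
    rs = None if seed is None else int(seed) % (2**32)
    if group_by_neuron:
        if features.source_ids is None:
            raise ParameterError("group_by_neuron requires source_ids")
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=rs)
        split_iter = splitter.split(features.values, labels, groups=features.source_ids)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        split_iter = splitter.split(features.values, labels)
    shared_pca = fit_pca(features, cpv=pca_cpv, n_components_override=n_components_override) if pca_global else None
    per_fold: List[ConfusionMatrix] = []
    fold_metrics: List[Dict] = []
    correct = np.zeros(features.n_spikes, dtype=bool)
    for fold_idx, (train_idx, test_idx) in enumerate(split_iter):
        model = train(
            features.subset(train_idx),
            clusters_per_class=clusters_per_class,
            pca_cpv=pca_cpv,
            n_components_override=n_components_override,
            fcm_m=fcm_m,
            fcm_tol=fcm_tol,
            fcm_max_iter=fcm_max_iter,
            seed=None if seed is None else (int(seed) + fold_idx) % (2**31),
            pca=shared_pca,
        )
        pred, _ = classify(model, features.subset(test_idx))
        true = labels[test_idx]
        correct[test_idx] = np.asarray(pred) == true
        cm = ConfusionMatrix.from_labels(true, pred, class_order)
        per_fold.append(cm)
        fold_metrics.append(class_metrics(cm))
    per_class = {
        cls: {
            metric: _mean_sem([fm["per_class"][cls][metric] for fm in fold_metrics])
            for metric in ("precision", "recall", "accuracy")
        }
        for cls in class_order
    }
    overall = {
        metric: _mean_sem([fm["overall"][metric] for fm in fold_metrics])
        for metric in ("precision", "recall", "accuracy")
    }
    config = {
        "k": k,
        "clusters_per_class": clusters_per_class,
        "pca_cpv": pca_cpv,
        "n_components_override": n_components_override,
        "fcm_m": fcm_m,
        "fcm_tol": fcm_tol,
        "fcm_max_iter": fcm_max_iter,
        "group_by_neuron": group_by_neuron,
        "pca_global": pca_global,
        "feature_kind": features.feature_kind,
    }
    return EvaluationReport(
        per_fold=per_fold,
        per_class=per_class,
        overall=overall,
        config=config,
        seed=seed,
        correct=correct,
        class_order=class_order,
    )


def mcnemar(
    correct_a: Sequence[bool], correct_b: Sequence[bool]
) -> Tuple[float, float]:
    """Continuity-corrected McNemar χ² for two paired classifiers.

    ``b`` counts items A got right and B wrong, ``c`` the reverse;
    the statistic is ``(|b−c|−1)² / (b+c)`` with 1 df.
    """
    a = np.asarray(correct_a, dtype=bool)
    b_arr = np.asarray(correct_b, dtype=bool)
    if a.shape != b_arr.shape:
        raise ParameterError("correctness vectors must have equal length")
    b = int(np.sum(a & ~b_arr))
    c = int(np.sum(~a & b_arr))
    if b + c == 0:
        warnings.warn("no discordant pairs; McNemar statistic undefined", stacklevel=2)
        return float("nan"), 1.0
    table = [[int(np.sum(a & b_arr)), b], [c, int(np.sum(~a & ~b_arr))]]
    res = _sm_mcnemar(table, exact=False, correction=True)
    return float(res.statistic), float(res.pvalue)


def cochran_q(correctness: np.ndarray) -> Tuple[float, float]:
    """Cochran's Q over an items × classifiers boolean matrix (χ², k−1 df)."""
    X = np.asarray(correctness, dtype=int)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ParameterError("cochran_q needs an items × (>=3 classifiers) matrix")
    row_sums = X.sum(axis=1)
    k = X.shape[1]
    if np.all((row_sums == 0) | (row_sums == k)):
        warnings.warn(
            "all items are unanimously right or wrong; Q degenerate", stacklevel=2
        )
        return 0.0, 1.0
    res = _sm_cochrans_q(X, return_object=True)
    stat, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(stat):
        warnings.warn("Cochran's Q undefined for this matrix", stacklevel=2)
        return float("nan"), 1.0
    return stat, p


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni adjustment: ``p_adj = min(1, p·m)``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ParameterError("bonferroni needs at least one p-value")
    return np.minimum(1.0, p * p.size)
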