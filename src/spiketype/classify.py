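"""Training the repository of labeled cluster centers and classifying spikes.

The semi-supervised scheme: standardization + correlation-matrix PCA are
fit on the labeled training features; fuzzy c-means (FCM) is then run
*within each class* in PC-score space and every resulting center is tagged
with its class label. A new spike is standardized, projected, and assigned
the class of the center at minimum Euclidean distance (ties break to the
earliest-stored center). A neuron-level call is the majority vote over its
spikes, ties resolved by the smaller mean winning distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial.distance import cdist

from .detect import SpikeSet
from .errors import NumericalError, ParameterError
from .features import FeatureMatrix, PCAModel, apply_pca, compute_features, fit_pca


@dataclass
class FCMResult:
    """Outcome of one fuzzy c-means run."""

    centers: np.ndarray  # c × d
    memberships: np.ndarray  # n × c, rows sum to 1
    objective_trace: np.ndarray  # per-iteration objective, non-increasing
    iterations: int
    converged: bool


@dataclass
class ClassifierModel:
    """The trained "repository": PCA parameters plus labeled cluster centers."""

    pca: PCAModel
    centers: np.ndarray  # in PC-score space
    center_labels: List[str]
    feature_config: Dict
    training_summary: Dict

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.shape[0] != len(self.center_labels):
            raise ParameterError("each center needs a class label")
        if self.centers.shape[1] != self.pca.q:
            raise ParameterError("center dimension must equal the retained PC count")


def fcm(
    points: Union[FeatureMatrix, np.ndarray],
    c: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> FCMResult:
    """Standard fuzzy c-means with seeded data-point initialization.

    Alternates membership updates (``u_ij ∝ d_ij^(-2/(m-1))``) and center
    updates (``u^m``-weighted means) until the largest center displacement
    drops below ``tol`` or ``max_iter`` is reached. Fully reproducible for
    a given seed.
    """
    X = points.values if isinstance(points, FeatureMatrix) else np.atleast_2d(
        np.asarray(points, dtype=float)
    )
    n = X.shape[0]
    if not 1 <= c <= n:
        raise ParameterError(f"need 1 <= c <= n, got c={c}, n={n}")
    if m <= 1:
        raise ParameterError(f"fuzzifier m must exceed 1, got {m}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = X[rng.choice(n, size=c, replace=False)].copy()
    exponent = 1.0 / (m - 1.0)
    objective: List[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = cdist(X, centers, metric="sqeuclidean")
        u = _memberships(d2, exponent)
        um = u**m
        weights = um.sum(axis=0)
        if np.any(weights == 0):  # an empty cluster: keep its old center
            new_centers = centers.copy()
            nz = weights > 0
            new_centers[nz] = (um[:, nz].T @ X) / weights[nz, None]
        else:
            new_centers = (um.T @ X) / weights[:, None]
        objective.append(float(np.sum(um * cdist(X, new_centers, metric="sqeuclidean"))))
        shift = float(np.max(np.linalg.norm(new_centers - centers, axis=1)))
        centers = new_centers
        if shift < tol:
            converged = True
            break
    d2 = cdist(X, centers, metric="sqeuclidean")
    u = _memberships(d2, exponent)
    return FCMResult(
        centers=centers,
        memberships=u,
        objective_trace=np.asarray(objective),
        iterations=it,
        converged=converged,
    )


def _memberships(d2: np.ndarray, exponent: float) -> np.ndarray:
    """Membership update; coincident point/center pairs get full membership."""
    if d2.shape[1] == 1:
        return np.ones_like(d2)
    zero_rows = np.any(d2 == 0, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-exponent)
        u = inv / inv.sum(axis=1, keepdims=True)
    if zero_rows.any():
        for i in np.flatnonzero(zero_rows):
            u[i] = 0.0
            hits = np.flatnonzero(d2[i] == 0)
            u[i, hits] = 1.0 / hits.size
    return u


def train(
    features: FeatureMatrix,
    clusters_per_class: int = 2,
    pca_cpv: float = 0.90,
    n_components_override: Optional[int] = None,
    fcm_m: float = 2.0,
    fcm_tol: float = 1e-5,
    fcm_max_iter: int = 300,
    seed: Optional[int] = None,
    pca: Optional[PCAModel] = None,
    feature_config: Optional[Dict] = None,
) -> ClassifierModel:
    """Fit PCA on labeled features and cluster each class in PC space.

    Parameters largely mirror :func:`fcm`; ``pca`` may be supplied to reuse
    a standardization/PCA fitted elsewhere (e.g. globally across folds).
    """
    if features.labels is None:
        raise ParameterError("training requires labeled features")
    if pca is None:
        pca = fit_pca(features, cpv=pca_cpv, n_components_override=n_components_override)
    scores = apply_pca(pca, features)
    labels = np.asarray(features.labels)
    classes = sorted(set(features.labels))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(classes))
    centers, center_labels = [], []
    summary: Dict[str, int] = {}
    for cls, child in zip(classes, children):
        idx = np.flatnonzero(labels == cls)
        summary[cls] = int(idx.size)
        if idx.size < clusters_per_class:
            raise ParameterError(
                f"class {cls!r} has {idx.size} spikes, fewer than "
                f"clusters_per_class={clusters_per_class}"
            )
        result = fcm(
            scores.values[idx],
            c=clusters_per_class,
            m=fcm_m,
            tol=fcm_tol,
            max_iter=fcm_max_iter,
            seed=np.random.default_rng(child),
        )
        centers.append(result.centers)
        center_labels.extend([cls] * clusters_per_class)
    config = dict(feature_config or {})
    config.setdefault("kind", features.feature_kind)
    config["d"] = features.d
    return ClassifierModel(
        pca=pca,
        centers=np.vstack(centers),
        center_labels=center_labels,
        feature_config=config,
        training_summary=summary,
    )


def classify(
    model: ClassifierModel, features: FeatureMatrix
) -> Tuple[List[str], np.ndarray]:
    """Assign each spike the class of its nearest stored center.

    Returns the class labels and the winning Euclidean distances (in
    PC-score space). Ties go to the earliest-stored center.
    """
    expected_d = model.feature_config.get("d", model.pca.d)
    if features.d != expected_d:
        raise ParameterError(
            f"feature dimension {features.d} does not match model ({expected_d})"
        )
    scores = apply_pca(model.pca, features)
    dist = cdist(scores.values, model.centers)
    winner = np.argmin(dist, axis=1)  # argmin takes the first minimum
    labels = [model.center_labels[i] for i in winner]
    return labels, dist[np.arange(dist.shape[0]), winner]


def classify_spikes(model: ClassifierModel, spikes: SpikeSet) -> Tuple[List[str], np.ndarray]:
    """Featurize a SpikeSet per the model's stored config, then classify."""
    config = {k: v for k, v in model.feature_config.items() if k not in ("kind", "d")}
    features = compute_features(spikes, model.feature_config.get("kind", "dct"), **config)
    return classify(model, features)


def classify_neuron(model: ClassifierModel, spikes: SpikeSet) -> str:
    """Cell-level call: majority vote over the neuron's per-spike labels.

    A vote tie resolves to the class with the smaller mean winning
    distance among its spikes.
    """
    if spikes.n_spikes == 0:
        raise ParameterError("cannot classify a neuron with no spikes")
    labels, distances = classify_spikes(model, spikes)
    return _vote(labels, distances)


def _vote(labels: Sequence[str], distances: np.ndarray) -> str:
    counts: Dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    top = max(counts.values())
    tied = [lab for lab, cnt in counts.items() if cnt == top]
    if len(tied) == 1:
        return tied[0]
    means = {
        lab: float(np.mean([d for l, d in zip(labels, distances) if l == lab]))
        for lab in tied
    }
    return min(tied, key=lambda lab: (means[lab], lab))
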