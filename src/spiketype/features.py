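"""Feature extraction from spike epochs.

Three feature families:

* **DCT coefficients** — each epoch is zero-padded at the tail to
  ``n_coeff`` samples (100 by default) and transformed by the DCT-II,
  ``v(k) = α(k) Σ_{n=0}^{N-1} u(n) cos((2n+1)πk / (2N))``. Two α
  conventions are available: ``"ortho"`` (α(0)=√(1/N), α(k≥1)=√(2/N); the
  orthonormal transform, energy-preserving) and ``"literal"``
  (α(k)=√((k+1)/N); a diagonal reweighting that emphasizes higher-order
  coefficients). The two differ only by a per-column scale, which
  correlation-matrix PCA removes, so the downstream classifier is
  identical under either; scatter-based separability (J3) is not.
* **AP-shape morphometry** — seven standard electrophysiological variables
  per spike: threshold (APT, dV/dt criterion), duration (APD, full width
  at half amplitude), afterhyperpolarization depth (AHP), 10–90% rise and
  90–10% fall times, and maximal rise/fall rates. Sub-sample level
  crossings are located by linear interpolation.
* **PC scores** — correlation-matrix PCA (features z-scored by training
  mean/SD) retaining the smallest number of components whose cumulative
  explained variance reaches the requested level (90% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import scipy.fft
from sklearn.decomposition import PCA as _SkPCA

from .detect import SpikeSet
from .errors import NumericalError, ParameterError

AP_SHAPE_COLUMNS = (
    "apt_mv",
    "apd_ms",
    "ahp_mv",
    "rt_ms",
    "ft_ms",
    "rr_v_per_s",
    "fr_v_per_s",
)


@dataclass
class FeatureMatrix:
    """Per-spike feature vectors with labels carried from the SpikeSet."""

    values: np.ndarray
    feature_kind: str  # "dct" | "ap_shape" | "pc_scores" | "raw"
    column_names: List[str]
    labels: Optional[List[str]] = None
    source_ids: Optional[List[str]] = None
    n_invalid: int = 0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.column_names):
            raise ParameterError("column_names must match the feature dimension")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("feature matrix contains non-finite values")
        n = self.values.shape[0]
        if self.labels is not None and len(self.labels) != n:
            raise ParameterError("labels must cover all rows")
        if self.source_ids is not None and len(self.source_ids) != n:
            raise ParameterError("source_ids must cover all rows")

    @property
    def n_spikes(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def subset(self, index: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(index)
        return FeatureMatrix(
            values=self.values[idx],
            feature_kind=self.feature_kind,
            column_names=list(self.column_names),
            labels=[self.labels[i] for i in idx] if self.labels is not None else None,
            source_ids=(
                [self.source_ids[i] for i in idx] if self.source_ids is not None else None
            ),
        )

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.column_names)
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        if self.source_ids is not None:
            df.insert(0, "source_id", self.source_ids)
        return df


def dct(u: Sequence[float], alpha: str = "ortho") -> np.ndarray:
    """DCT-II of a real sequence under the chosen α convention."""
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or u.size == 0:
        raise ParameterError("dct expects a non-empty 1-D sequence")
    n = u.size
    if alpha == "ortho":
        return scipy.fft.dct(u, type=2, norm="ortho")
    if alpha == "literal":
        # scipy's unnormalized DCT-II is 2·Σ u(n) cos(...); rescale to
        # α(k) = sqrt((k+1)/N).
        raw = scipy.fft.dct(u, type=2, norm=None) / 2.0
        k = np.arange(n)
        return np.sqrt((k + 1) / n) * raw
    raise ParameterError(f"unknown dct alpha convention {alpha!r}")


def dct_features(
    spikes: SpikeSet, n_coeff: int = 100, alpha: str = "ortho"
) -> FeatureMatrix:
    """Zero-pad each epoch at the tail to ``n_coeff`` samples and DCT it."""
    w = spikes.waveforms.shape[1]
    if w > n_coeff:
        raise ParameterError(f"rows of {w} samples exceed n_coeff={n_coeff}")
    padded = np.zeros((spikes.n_spikes, n_coeff))
    padded[:, :w] = spikes.waveforms
    if alpha == "ortho":
        values = scipy.fft.dct(padded, type=2, norm="ortho", axis=1)
    else:
        values = np.apply_along_axis(dct, 1, padded, alpha)
    return FeatureMatrix(
        values=values,
        feature_kind="dct",
        column_names=[f"dct_{k}" for k in range(n_coeff)],
        labels=list(spikes.labels) if spikes.labels is not None else None,
        source_ids=list(spikes.source_ids),
    )


def raw_features(spikes: SpikeSet) -> FeatureMatrix:
    """The raw epoch samples themselves, as a feature matrix."""
    return FeatureMatrix(
        values=spikes.waveforms.copy(),
        feature_kind="raw",
        column_names=[f"s{j}" for j in range(spikes.waveforms.shape[1])],
        labels=list(spikes.labels) if spikes.labels is not None else None,
        source_ids=list(spikes.source_ids),
    )


def _cross_time(x: np.ndarray, i: int, level: float) -> float:
    """Sub-sample time of the crossing of `level` between samples i, i+1."""
    x0, x1 = x[i], x[i + 1]
    if x1 == x0:
        return float(i)
    return i + (level - x0) / (x1 - x0)


def _rising_cross(x: np.ndarray, level: float, stop: int) -> Optional[float]:
    """Last upward crossing of `level` strictly before sample `stop`."""
    for i in range(stop - 1, -1, -1):
        if x[i] <= level <= x[i + 1] and x[i + 1] > x[i]:
            return _cross_time(x, i, level)
    return None


def _falling_cross(x: np.ndarray, level: float, start: int) -> Optional[float]:
    """First downward crossing of `level` at or after sample `start`."""
    for i in range(start, x.size - 1):
        if x[i] >= level >= x[i + 1] and x[i + 1] < x[i]:
            return _cross_time(x, i, level)
    return None


def ap_shape_features(
    spikes: SpikeSet, dvdt_threshold_v_per_s: float = 10.0
) -> FeatureMatrix:
    """Measure the seven AP morphometric variables for each epoch.

    Rows where a variable is unmeasurable (no dV/dt threshold crossing
    before the peak, no half-amplitude crossing inside the window, or
    non-positive amplitude) are dropped and counted in ``n_invalid``; an
    all-invalid set raises :class:`NumericalError`.
    """
    fs = spikes.fs
    p = spikes.peak_offset
    ms_per_sample = 1000.0 / fs
    rows, keep = [], []
    for r in range(spikes.n_spikes):
        x = spikes.waveforms[r]
        # dV/dt in V/s: central differences inside, one-sided at the edges.
        dv = np.gradient(x) * fs / 1000.0
        feats = _shape_one(x, dv, p, dvdt_threshold_v_per_s, ms_per_sample)
        if feats is None:
            continue
        rows.append(feats)
        keep.append(r)
    n_invalid = spikes.n_spikes - len(rows)
    if not rows:
        raise NumericalError(
            "no spike yielded a valid AP-shape measurement "
            f"({n_invalid} invalid rows)"
        )
    if n_invalid:
        warnings.warn(f"{n_invalid} spikes had unmeasurable AP shape; dropped", stacklevel=2)
    keep_arr = np.asarray(keep)
    return FeatureMatrix(
        values=np.asarray(rows),
        feature_kind="ap_shape",
        column_names=list(AP_SHAPE_COLUMNS),
        labels=(
            [spikes.labels[i] for i in keep_arr] if spikes.labels is not None else None
        ),
        source_ids=[spikes.source_ids[i] for i in keep_arr],
        n_invalid=n_invalid,
    )


def _shape_one(x, dv, p, dvdt_thr, ms_per_sample):
    # APT: voltage where dV/dt first reaches threshold before the peak; the
    # crossing is located between samples by linear interpolation (a
    # sample-resolution APT carries an up-to-one-sample bias into AHP).
    pre = np.flatnonzero(dv[: p + 1] >= dvdt_thr)
    if pre.size == 0:
        return None
    i = pre[0]
    if i == 0:
        apt = x[0]
    else:
        frac = (dvdt_thr - dv[i - 1]) / (dv[i] - dv[i - 1])
        apt = x[i - 1] + frac * (x[i] - x[i - 1])
    amplitude = x[p] - apt
    if amplitude <= 0:
        return None
    half = apt + amplitude / 2.0
    t_rise_half = _rising_cross(x, half, p)
    t_fall_half = _falling_cross(x, half, p)
    if t_rise_half is None or t_fall_half is None:
        return None
    apd = (t_fall_half - t_rise_half) * ms_per_sample
    # AHP relative to threshold, floored at zero.
    ahp = max(0.0, apt - float(np.min(x[p:])))
    l10 = apt + 0.1 * amplitude
    l90 = apt + 0.9 * amplitude
    t10r = _rising_cross(x, l10, p)
    t90r = _rising_cross(x, l90, p)
    t90f = _falling_cross(x, l90, p)
    t10f = _falling_cross(x, l10, p)
    if None in (t10r, t90r, t90f, t10f):
        return None
    rt = (t90r - t10r) * ms_per_sample
    ft = (t10f - t90f) * ms_per_sample
    rr = float(np.max(dv))
    fr = float(abs(np.min(dv)))
    return [apt, apd, ahp, rt, ft, rr, fr]


@dataclass
class PCAModel:
    """Correlation-matrix PCA: standardization plus retained components."""

    center: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # q × d, rows orthonormal
    explained_ratio: np.ndarray  # q fractions, non-increasing
    eigenvalues: np.ndarray  # full spectrum of the correlation matrix
    q: int
    cpv_threshold: float

    @property
    def d(self) -> int:
        return self.center.size


def fit_pca(
    features: FeatureMatrix,
    cpv: float = 0.90,
    n_components_override: Optional[int] = None,
) -> PCAModel:
    """Fit correlation-matrix PCA and choose how many components to keep.

    Columns are z-scored by the training mean and (ddof=1) SD, so the
    covariance of the standardized data is the correlation matrix and its
    eigenvalues sum to the feature dimension. Retains the smallest ``q``
    with cumulative explained variance ≥ ``cpv`` unless an explicit
    ``n_components_override`` is given. Sign convention: each component's
    largest-magnitude loading is positive.
    """
    X = features.values
    n, d = X.shape
    if n < 2:
        raise ParameterError("PCA needs at least 2 rows")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    # a constant column's std is ~eps*|mean|, not exactly 0
    zero_var = scale <= 1e-12 * np.maximum(1.0, np.abs(center))
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance feature column(s); scale set to 1",
            stacklevel=2,
        )
        scale = np.where(zero_var, 1.0, scale)
    Z = (X - center) / scale
    sk = _SkPCA(n_components=None, svd_solver="full")
    sk.fit(Z)
    eigenvalues = sk.explained_variance_
    ratios = sk.explained_variance_ratio_
    if n_components_override is not None:
        q = int(n_components_override)
        if not 1 <= q <= ratios.size:
            raise ParameterError(f"n_components_override={q} outside [1, {ratios.size}]")
    else:
        q = int(np.searchsorted(np.cumsum(ratios), cpv) + 1)
        q = min(q, ratios.size)
    components = sk.components_[:q].copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCAModel(
        center=center,
        scale=scale,
        components=components,
        explained_ratio=ratios[:q].copy(),
        eigenvalues=eigenvalues.copy(),
        q=q,
        cpv_threshold=float(cpv),
    )


def apply_pca(model: PCAModel, features: FeatureMatrix) -> FeatureMatrix:
    """Project features onto the stored components (no re-fitting)."""
    if features.d != model.d:
        raise ParameterError(
            f"feature dimension {features.d} does not match PCA model ({model.d})"
        )
    Z = (features.values - model.center) / model.scale
    scores = Z @ model.components.T
    return FeatureMatrix(
        values=scores,
        feature_kind="pc_scores",
        column_names=[f"pc{i + 1}" for i in range(model.q)],
        labels=list(features.labels) if features.labels is not None else None,
        source_ids=list(features.source_ids) if features.source_ids is not None else None,
    )


def compute_features(spikes: SpikeSet, kind: str, **config) -> FeatureMatrix:
    """Dispatch on feature kind; used by the pipeline and saved models."""
    if kind == "dct":
        return dct_features(
            spikes,
            n_coeff=int(config.get("n_coeff", 100)),
            alpha=config.get("alpha", "ortho"),
        )
    if kind == "ap_shape":
        return ap_shape_features(
            spikes,
            dvdt_threshold_v_per_s=float(config.get("dvdt_threshold_v_per_s", 10.0)),
        )
    if kind == "raw":
        return raw_features(spikes)
    raise ParameterError(f"unknown feature kind {kind!r}")
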