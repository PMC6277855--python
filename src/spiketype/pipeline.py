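"""End-to-end orchestration of the classification pipeline.

``run_pipeline`` wires preprocess → detect → extract → features →
(train | predict | evaluate) from a single :class:`RunConfig`, logging
per-stage record counts so runs are auditable: the number of traces read,
spikes detected, spikes skipped at epoch edges, and spikes classified.
Identical config + seed gives identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from . import detect as _detect
from . import evaluate as _evaluate
from . import features as _features
from . import io as _io
from .classify import classify_spikes as _classify_spikes
from .classify import train as _train
from .classify import _vote
from .errors import ParameterError, SpikeTypeError
from .preprocess import preprocess as _preprocess_trace

log = logging.getLogger("spiketype")


@dataclass
class RunConfig:
    """All stage parameters for one pipeline run."""

    mode: str = "evaluate"  # train | predict | evaluate
    trace_paths: List[str] = field(default_factory=list)
    model_path: Optional[str] = None
    out_path: Optional[str] = None
    # preprocessing
    notch: bool = True
    notch_hz: float = 50.0
    notch_bw: float = 5.0
    notch_order: int = 3
    smooth: bool = True
    smooth_ms: float = 0.4
    # detection / extraction
    threshold_mv: float = -20.0
    min_isi_ms: float = 2.0
    pre_ms: float = 1.0
    post_ms: float = 2.0
    # features
    feature_kind: str = "dct"
    n_coeff: int = 100
    dct_alpha: str = "ortho"
    dvdt_threshold_v_per_s: float = 10.0
    # PCA / FCM / CV
    pca_cpv: float = 0.90
    n_components: Optional[int] = None
    clusters_per_class: int = 2
    fcm_m: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 300
    folds: int = 10
    group_by_neuron: bool = False
    pca_global: bool = False
    seed: Optional[int] = None

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


def traces_to_spikes(config: RunConfig, counts: Optional[Dict] = None) -> _detect.SpikeSet:
    """Read, denoise, detect, and extract across all configured traces."""
    if not config.trace_paths:
        raise ParameterError("no input trace files given")
    counts = counts if counts is not None else {}
    parts = []
    n_detected = n_skipped = 0
    for path in config.trace_paths:
        trace = _io.read_trace(path)
        trace = _preprocess_trace(
            trace,
            notch=config.notch,
            smooth=config.smooth,
            center_hz=config.notch_hz,
            bandwidth_hz=config.notch_bw,
            order=config.notch_order,
            window_ms=config.smooth_ms,
        )
        markers = _detect.detect_peaks(
            trace, threshold_mv=config.threshold_mv, min_isi_ms=config.min_isi_ms
        )
        spikes = _detect.extract_spikes(
            trace, markers, pre_ms=config.pre_ms, post_ms=config.post_ms
        )
        n_detected += len(markers)
        n_skipped += spikes.n_skipped
        parts.append(spikes)
        log.info(
            "%s: %d peaks, %d extracted, %d skipped at edges",
            path, len(markers), spikes.n_spikes, spikes.n_skipped,
        )
    merged = _detect.SpikeSet.concat(parts)
    counts.update(
        traces_read=len(config.trace_paths),
        spikes_detected=n_detected,
        spikes_extracted=merged.n_spikes,
        spikes_skipped_at_edges=n_skipped,
    )
    return merged


def spikes_to_features(config: RunConfig, spikes: _detect.SpikeSet) -> _features.FeatureMatrix:
    return _features.compute_features(
        spikes,
        config.feature_kind,
        n_coeff=config.n_coeff,
        alpha=config.dct_alpha,
        dvdt_threshold_v_per_s=config.dvdt_threshold_v_per_s,
    )


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the configured mode; returns a JSON-serializable summary."""
    counts: Dict = {}
    result: Dict = {"mode": config.mode, "config": config.to_dict()}
    spikes = traces_to_spikes(config, counts)
    feats = spikes_to_features(config, spikes)
    counts["spikes_featurized"] = feats.n_spikes

    if config.mode == "train":
        model = _train(
            feats,
            clusters_per_class=config.clusters_per_class,
            pca_cpv=config.pca_cpv,
            n_components_override=config.n_components,
            fcm_m=config.fcm_m,
            fcm_tol=config.fcm_tol,
            fcm_max_iter=config.fcm_max_iter,
            seed=config.seed,
            feature_config=_feature_config(config),
        )
        if not config.model_path:
            raise ParameterError("train mode requires a model output path")
        _io.save_model(model, config.model_path)
        result["model_path"] = str(config.model_path)
        result["training_summary"] = model.training_summary
    elif config.mode == "predict":
        if not config.model_path:
            raise ParameterError("predict mode requires a model file")
        model = _io.load_model(config.model_path)
        labels, distances = _classify_spikes(model, spikes)
        counts["spikes_classified"] = len(labels)
        per_neuron = {}
        for nid in sorted(set(spikes.source_ids)):
            idx = [i for i, s in enumerate(spikes.source_ids) if s == nid]
            sub_labels = [labels[i] for i in idx]
            sub_dist = distances[idx]
            per_neuron[nid] = _vote(sub_labels, sub_dist)
        result["per_spike_labels"] = labels
        result["per_neuron_labels"] = per_neuron
    elif config.mode == "evaluate":
        report = _evaluate.cross_validate(
            feats,
            k=config.folds,
            clusters_per_class=config.clusters_per_class,
            pca_cpv=config.pca_cpv,
            n_components_override=config.n_components,
            fcm_m=config.fcm_m,
            fcm_tol=config.fcm_tol,
            fcm_max_iter=config.fcm_max_iter,
            seed=config.seed,
            group_by_neuron=config.group_by_neuron,
            pca_global=config.pca_global,
        )
        result["report"] = report.to_dict()
    else:
        raise ParameterError(f"unknown pipeline mode {config.mode!r}")

    result["counts"] = counts
    if config.out_path:
        out = Path(config.out_path)
        out.parent.mkdir(parents=True, exist_ok=True)
        with open(out, "w") as fh:
            json.dump(result, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return result


def _feature_config(config: RunConfig) -> Dict:
    if config.feature_kind == "dct":
        return {"kind": "dct", "n_coeff": config.n_coeff, "alpha": config.dct_alpha}
    if config.feature_kind == "ap_shape":
        return {"kind": "ap_shape", "dvdt_threshold_v_per_s": config.dvdt_threshold_v_per_s}
    return {"kind": config.feature_kind}
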