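"""Reading and writing voltage traces, spike matrices, and trained models.

File formats are deliberately minimal, documented, plain text:

* **Trace files** — lines beginning with ``#`` hold ``key=value`` metadata
  (``fs_hz`` is required; ``units`` must be ``mV``); every following
  non-empty line is one voltage sample in mV, either a single column or a
  two-column ``time,voltage`` pair (the time column is ignored and the
  spacing assumed uniform at ``fs``).
* **SpikeSet files** — ``#`` header with ``fs_hz``, ``pre_ms``, ``post_ms``
  and layout flags; one tab-separated spike per row, optionally prefixed by
  a source-neuron id and class label.
* **Model files** — JSON carrying a schema version, the feature
  configuration, standardization and PCA parameters, and the labeled
  cluster centers (the classifier's "repository"). Readers reject unknown
  versions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import FormatError, ModelVersionError, ParameterError

MODEL_FORMAT_NAME = "spiketype-model"
MODEL_FORMAT_VERSION = "1"

# %.17g round-trips IEEE doubles exactly, comfortably above the documented
# 12-significant-digit guarantee.
_FLOAT_FMT = "%.17g"


@dataclass
class TraceMetadata:
    """Acquisition metadata attached to a single-neuron voltage trace."""

    fs: float
    units: str = "mV"
    neuron_id: str = ""
    class_label: Optional[str] = None

    def validate(self) -> None:
        if not (self.fs > 0 and math.isfinite(self.fs)):
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if self.units != "mV":
            raise ParameterError(f"voltage units must be 'mV', got {self.units!r}")


@dataclass
class Trace:
    """One neuron's membrane-potential time series in mV."""

    samples: np.ndarray
    meta: TraceMetadata

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.validate()

    def validate(self) -> None:
        self.meta.validate()
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ParameterError(
                f"trace must be a 1-D series of >= 2 samples, got shape {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("trace contains non-finite samples")

    @property
    def fs(self) -> float:
        return self.meta.fs

    def with_samples(self, samples: np.ndarray) -> "Trace":
        return Trace(samples=np.asarray(samples, dtype=float), meta=replace(self.meta))


def _parse_header(lines) -> dict:
    header = {}
    for raw in lines:
        body = raw.lstrip("#").strip()
        if not body or "=" not in body:
            continue
        key, _, value = body.partition("=")
        header[key.strip()] = value.strip()
    return header


def read_trace(path) -> Trace:
    """Read a trace file; see the module docstring for the format."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"trace file not found: {path}")
    header_lines, samples = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header_lines.append(line)
                continue
            parts = line.replace(",", " ").split()
            try:
                value = float(parts[-1])  # last column = voltage
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric sample line {line!r}"
                ) from None
            samples.append(value)
    header = _parse_header(header_lines)
    if "fs_hz" not in header:
        raise FormatError(f"{path}: missing required header key fs_hz")
    try:
        fs = float(header["fs_hz"])
    except ValueError:
        raise FormatError(f"{path}: fs_hz is not numeric: {header['fs_hz']!r}") from None
    meta = TraceMetadata(
        fs=fs,
        units=header.get("units", "mV"),
        neuron_id=header.get("neuron_id", ""),
        class_label=header.get("class_label") or None,
    )
    try:
        return Trace(samples=np.asarray(samples, dtype=float), meta=meta)
    except ParameterError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_trace(trace: Trace, path) -> None:
    """Write a trace readable by :func:`read_trace` (full float precision)."""
    trace.validate()
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={_FLOAT_FMT % trace.meta.fs}\n")
        fh.write(f"# units={trace.meta.units}\n")
        if trace.meta.neuron_id:
            fh.write(f"# neuron_id={trace.meta.neuron_id}\n")
        if trace.meta.class_label is not None:
            fh.write(f"# class_label={trace.meta.class_label}\n")
        for v in trace.samples:
            fh.write(_FLOAT_FMT % v + "\n")


# ---------------------------------------------------------------------------
# SpikeSet files


def write_spikes(spikes, path) -> None:
    """Write a :class:`~spiketype.detect.SpikeSet`, one spike per row."""
    path = Path(path)
    has_labels = spikes.labels is not None
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={_FLOAT_FMT % spikes.fs}\n")
        fh.write(f"# pre_ms={_FLOAT_FMT % spikes.pre_ms}\n")
        fh.write(f"# post_ms={_FLOAT_FMT % spikes.post_ms}\n")
        fh.write(f"# peak_offset={spikes.peak_offset}\n")
        fh.write(f"# has_labels={int(has_labels)}\n")
        fh.write("# columns=source_id" + ("\tlabel" if has_labels else "") + "\tv0...\n")
        for i, row in enumerate(spikes.waveforms):
            cells = [str(spikes.source_ids[i])]
            if has_labels:
                cells.append(str(spikes.labels[i]))
            cells.extend(_FLOAT_FMT % v for v in row)
            fh.write("\t".join(cells) + "\n")


def read_spikes(path):
    """Read a SpikeSet file written by :func:`write_spikes`."""
    from .detect import SpikeSet  # deferred to avoid an import cycle

    path = Path(path)
    if not path.exists():
        raise FormatError(f"spike file not found: {path}")
    header_lines, rows = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                header_lines.append(line)
                continue
            rows.append((lineno, line.split("\t")))
    header = _parse_header(header_lines)
    for key in ("fs_hz", "pre_ms", "post_ms", "peak_offset"):
        if key not in header:
            raise FormatError(f"{path}: missing required header key {key}")
    has_labels = header.get("has_labels", "0") == "1"
    n_meta = 2 if has_labels else 1
    source_ids, labels, waveforms = [], [], []
    for lineno, cells in rows:
        if len(cells) <= n_meta:
            raise FormatError(f"{path}:{lineno}: too few columns")
        source_ids.append(cells[0])
        if has_labels:
            labels.append(cells[1])
        try:
            waveforms.append([float(c) for c in cells[n_meta:]])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric waveform value") from None
    return SpikeSet(
        waveforms=np.asarray(waveforms, dtype=float),
        peak_offset=int(header["peak_offset"]),
        fs=float(header["fs_hz"]),
        pre_ms=float(header["pre_ms"]),
        post_ms=float(header["post_ms"]),
        source_ids=source_ids,
        labels=labels if has_labels else None,
    )


# ---------------------------------------------------------------------------
# Model files


def save_model(model, path) -> None:
    """Serialize a trained :class:`~spiketype.classify.ClassifierModel` to JSON."""
    pca = model.pca
    payload = {
        "format": MODEL_FORMAT_NAME,
        "version": MODEL_FORMAT_VERSION,
        "feature_config": model.feature_config,
        "pca": {
            "center": pca.center.tolist(),
            "scale": pca.scale.tolist(),
            "components": pca.components.tolist(),
            "explained_ratio": pca.explained_ratio.tolist(),
            "eigenvalues": pca.eigenvalues.tolist(),
            "q": int(pca.q),
            "cpv_threshold": float(pca.cpv_threshold),
        },
        "centers": model.centers.tolist(),
        "center_labels": list(model.center_labels),
        "training_summary": model.training_summary,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path):
    """Load a model file, rejecting unknown schema versions."""
    from .classify import ClassifierModel
    from .features import PCAModel

    path = Path(path)
    if not path.exists():
        raise FormatError(f"model file not found: {path}")
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid model JSON ({exc})") from exc
    if payload.get("format") != MODEL_FORMAT_NAME:
        raise FormatError(f"{path}: not a {MODEL_FORMAT_NAME} file")
    version = payload.get("version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelVersionError(
            f"{path}: unsupported model version {version!r} "
            f"(this build reads version {MODEL_FORMAT_VERSION!r})"
        )
    try:
        p = payload["pca"]
        pca = PCAModel(
            center=np.asarray(p["center"], dtype=float),
            scale=np.asarray(p["scale"], dtype=float),
            components=np.asarray(p["components"], dtype=float),
            explained_ratio=np.asarray(p["explained_ratio"], dtype=float),
            eigenvalues=np.asarray(p["eigenvalues"], dtype=float),
            q=int(p["q"]),
            cpv_threshold=float(p["cpv_threshold"]),
        )
        return ClassifierModel(
            pca=pca,
            centers=np.asarray(payload["centers"], dtype=float),
            center_labels=list(payload["center_labels"]),
            feature_config=dict(payload["feature_config"]),
            training_summary=dict(payload["training_summary"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed model payload ({exc})") from exc
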