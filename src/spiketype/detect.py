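"""Threshold-based action-potential detection and epoch extraction.

A spike marker is the sample index of the maximum of each contiguous
supra-threshold excursion of the trace. Around each marker a fixed window
(default −1 ms to +2 ms) is cut as one epoch; at 20 kHz that is exactly 60
samples with the peak at offset 20. The window is half-open,
``[t - round(pre*fs/1000), t + round(post*fs/1000))``, which reconciles a
"3 ms" window with an exact 60-sample epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .errors import ParameterError
from .io import Trace


@dataclass
class SpikeMarkers:
    """Detected AP peak positions for one trace."""

    peak_indices: np.ndarray
    threshold_mv: float
    fs: float

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=np.int64)
        if self.peak_indices.size > 1 and not np.all(np.diff(self.peak_indices) > 0):
            raise ParameterError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.peak_indices.size)


@dataclass
class SpikeSet:
    """Aligned spike epochs (one per row) with provenance.

    ``waveforms`` is ``n_spikes × w`` in mV; ``peak_offset`` is the in-row
    sample index of the AP peak; ``labels`` (optional) and ``source_ids``
    carry one entry per row.
    """

    waveforms: np.ndarray
    peak_offset: int
    fs: float
    pre_ms: float
    post_ms: float
    source_ids: List[str] = field(default_factory=list)
    labels: Optional[List[str]] = None
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=float))
        if self.waveforms.size == 0:
            self.waveforms = self.waveforms.reshape(0, self.expected_width())
        w = self.waveforms.shape[1]
        if w != self.expected_width():
            raise ParameterError(
                f"rows have {w} samples, expected "
                f"round(({self.pre_ms}+{self.post_ms}) ms * {self.fs} Hz) = "
                f"{self.expected_width()}"
            )
        if not 0 <= self.peak_offset < w:
            raise ParameterError(f"peak_offset {self.peak_offset} outside rows of width {w}")
        n = self.waveforms.shape[0]
        if not self.source_ids:
            self.source_ids = [""] * n
        if len(self.source_ids) != n:
            raise ParameterError("source_ids must cover all rows")
        if self.labels is not None and len(self.labels) != n:
            raise ParameterError("labels, when present, must cover all rows")

    def expected_width(self) -> int:
        return int(round((self.pre_ms + self.post_ms) * self.fs / 1000.0))

    @property
    def n_spikes(self) -> int:
        return self.waveforms.shape[0]

    def __len__(self) -> int:
        return self.n_spikes

    @staticmethod
    def concat(parts: Sequence["SpikeSet"]) -> "SpikeSet":
        """Stack several compatible spike sets into one."""
        parts = [p for p in parts]
        if not parts:
            raise ParameterError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if (p.fs, p.pre_ms, p.post_ms, p.peak_offset) != (
                first.fs,
                first.pre_ms,
                first.post_ms,
                first.peak_offset,
            ):
                raise ParameterError("incompatible spike sets (window or rate differs)")
        labels: Optional[List[str]]
        if all(p.labels is not None for p in parts):
            labels = [lab for p in parts for lab in p.labels]  # type: ignore[union-attr]
        else:
            labels = None
        return SpikeSet(
            waveforms=np.vstack([p.waveforms for p in parts]),
            peak_offset=first.peak_offset,
            fs=first.fs,
            pre_ms=first.pre_ms,
            post_ms=first.post_ms,
            source_ids=[s for p in parts for s in p.source_ids],
            labels=labels,
            n_skipped=sum(p.n_skipped for p in parts),
        )


def detect_peaks(
    trace: Trace, threshold_mv: float, min_isi_ms: float = 2.0
) -> SpikeMarkers:
    """Place one marker at the maximum of each supra-threshold excursion.

    Plateau maxima resolve to the earliest sample. Excursions whose peaks
    fall closer than ``min_isi_ms`` keep only the larger peak.
    """
    x = trace.samples
    fs = trace.fs
    above = x >= threshold_mv
    if not above.any():
        return SpikeMarkers(np.empty(0, dtype=np.int64), threshold_mv, fs)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.insert(starts, 0, 0)
    if above[-1]:
        ends = np.append(ends, x.size)
    candidates = np.array(
        [s + int(np.argmax(x[s:e])) for s, e in zip(starts, ends)], dtype=np.int64
    )
    min_isi = int(round(min_isi_ms * fs / 1000.0))
    if min_isi > 1 and candidates.size > 1:
        # Greedily accept the tallest peaks first (earliest index on ties),
        # rejecting any candidate within min_isi of an accepted peak.
        order = np.lexsort((candidates, -x[candidates]))
        accepted: List[int] = []
        for idx in candidates[order]:
            if all(abs(int(idx) - a) >= min_isi for a in accepted):
                accepted.append(int(idx))
        candidates = np.sort(np.asarray(accepted, dtype=np.int64))
    return SpikeMarkers(candidates, threshold_mv, fs)


def extract_spikes(
    trace: Trace,
    markers: SpikeMarkers,
    pre_ms: float = 1.0,
    post_ms: float = 2.0,
) -> SpikeSet:
    """Cut the half-open window ``[t-pre, t+post)`` around each marker.

    Markers too close to either trace edge are skipped and counted in the
    returned set's ``n_skipped``. Row values are exact copies of the trace.
    """
    fs = trace.fs
    pre = int(round(pre_ms * fs / 1000.0))
    post = int(round(post_ms * fs / 1000.0))
    if pre + post < 2:
        raise ParameterError("extraction window shorter than two samples")
    rows = []
    skipped = 0
    for t in markers.peak_indices:
        t = int(t)
        if t - pre < 0 or t + post > trace.samples.size:
            skipped += 1
            continue
        rows.append(trace.samples[t - pre : t + post])
    if not rows:
        warnings.warn(
            f"no extractable spikes ({skipped} markers skipped at trace edges)",
            stacklevel=2,
        )
        waveforms = np.empty((0, pre + post))
    else:
        waveforms = np.vstack(rows)
    n = waveforms.shape[0]
    label = trace.meta.class_label
    return SpikeSet(
        waveforms=waveforms,
        peak_offset=pre,
        fs=fs,
        pre_ms=pre_ms,
        post_ms=post_ms,
        source_ids=[trace.meta.neuron_id] * n,
        labels=[label] * n if label is not None else None,
        n_skipped=skipped,
    )
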