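"""Denoising of raw membrane-potential traces.

Two steps, applied in this order: a zero-phase Butterworth band-stop
("notch") around the power-line frequency, then a short centered moving
average. The notch is an order-3 Butterworth band-stop with edges
``center ± bandwidth/2`` run forward and backward (``sosfiltfilt``), so the
net phase shift is zero and the stop-band attenuation is doubled.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .errors import ParameterError
from .io import Trace


def notch_filter(
    trace: Trace,
    center_hz: float = 50.0,
    bandwidth_hz: float = 5.0,
    order: int = 3,
) -> Trace:
    """Remove line interference with a zero-phase Butterworth band-stop.

    Parameters
    ----------
    trace : Trace
        Input voltage trace.
    center_hz : float
        Center of the stop band (50 Hz mains by default).
    bandwidth_hz : float
        Full stop-band width; edges are ``center ± bandwidth/2``.
    order : int
        Order of the Butterworth prototype.

    Returns
    -------
    Trace
        Same-length filtered trace.
    """
    fs = trace.fs
    lo = center_hz - bandwidth_hz / 2.0
    hi = center_hz + bandwidth_hz / 2.0
    if lo <= 0 or fs <= 2.0 * hi:
        raise ParameterError(
            f"sampling rate {fs} Hz too low for a [{lo}, {hi}] Hz stop band"
        )
    # Second-order sections for numerical stability; sosfiltfilt's default
    # odd-reflection padding mitigates edge transients.
    sos = signal.butter(order, [lo, hi], btype="bandstop", fs=fs, output="sos")
    return trace.with_samples(signal.sosfiltfilt(sos, trace.samples))


def moving_average(trace: Trace, window_ms: float = 0.4) -> Trace:
    """Centered boxcar smoothing with reflection-padded edges.

    The window length is ``L = round(window_ms * fs / 1000)`` samples. For
    even ``L`` the window is split asymmetrically: ``floor(L/2)`` samples
    before the center sample and the remainder after (a fixed convention so
    outputs are reproducible).
    """
    fs = trace.fs
    L = int(round(window_ms * fs / 1000.0))
    if L < 1:
        raise ParameterError(
            f"window {window_ms} ms is shorter than one sample at {fs} Hz"
        )
    if L >= trace.samples.size:
        raise ParameterError(
            f"window of {L} samples is not shorter than the trace "
            f"({trace.samples.size} samples)"
        )
    if L == 1:
        return trace.with_samples(trace.samples.copy())
    before = L // 2
    after = L - 1 - before
    padded = np.pad(trace.samples, (before, after), mode="reflect")
    smoothed = np.convolve(padded, np.full(L, 1.0 / L), mode="valid")
    return trace.with_samples(smoothed)


def preprocess(
    trace: Trace,
    notch: bool = True,
    smooth: bool = True,
    center_hz: float = 50.0,
    bandwidth_hz: float = 5.0,
    order: int = 3,
    window_ms: float = 0.4,
) -> Trace:
    """Apply the standard denoising chain: notch first, then moving average."""
    out = trace
    if notch:
        out = notch_filter(out, center_hz=center_hz, bandwidth_hz=bandwidth_hz, order=order)
    if smooth:
        out = moving_average(out, window_ms=window_ms)
    return out
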