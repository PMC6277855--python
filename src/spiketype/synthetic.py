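"""Synthetic class-conditioned action potentials, spike trains, and traces.

The waveform family is chosen so that every generator parameter maps
one-to-one onto a measured AP-shape feature, allowing closed-loop
verification of the whole pipeline:

* rise and fall limbs are quarter-cosine lobes, ``A·cos(πs/(2w))``; a lobe
  of support ``w`` has its half-maximum at ``2w/3``, so the supports are
  set from the requested full width at half maximum (``apd_ms``) and the
  rise/fall asymmetry (``rise_fall_ratio``). Compact support (1.5× the
  half-width at half maximum per limb) guarantees the spike repolarizes
  inside the −1/+2 ms epoch even for broad pyramidal-like spikes, leaving
  room for the afterhyperpolarization trough;
* the AHP is a smooth undershoot below threshold whose trough depth is
  exactly ``ahp_mv``; its *time course* — onset sharpness ``ahp_onset_ms``
  and exponential decay ``ahp_tau_ms`` — is class-conditioned. These two
  dimensions are deliberately invisible to the seven morphometric scalars
  (which capture depth but not kinetics) while remaining visible to any
  full-waveform representation: fast-spiking PV cells get a fast,
  sharp-onset AHP, pyramidal cells a slow one, mirroring the classic
  fAHP/mAHP contrast. Without them the seven morphometric parameters
  would be sufficient statistics of the generative model, which real
  spike waveforms are not;
* per-spike variability is multiplicative jitter (coefficient of
  variation ``jitter_cv``) on the shape parameters;
* traces place spikes by exponential inter-spike intervals above a 10 ms
  refractory floor and add Gaussian noise plus a 50 Hz line-interference
  sinusoid; short cosine ramps tie the spike's threshold baseline to the
  resting potential outside the epoch so the trace has no steps.

Default shape parameters for the three-class preset (``paper3``) use the
reported class-typical AP duration and AHP depth for parvalbumin (PV),
somatostatin (SST) and pyramidal (Pyr) neurons; parameters with no
reported value (rest −65 mV, amplitude 65 mV, per-class threshold,
jitter 0.05, noise SD 0.5 mV) are this package's own calibration and are
flagged in the manifest. The ``allen5`` preset adds VIP and 5HT3a classes
with interpolated shapes (synthetic stand-ins, not derived from any
recorded dataset).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import ParameterError
from .io import Trace, TraceMetadata

_REFRACTORY_MS = 10.0
_PRE_RAMP_MS = 2.0
_POST_RAMP_MS = 4.0
_WINDOW_PRE_MS = 1.0
_WINDOW_POST_MS = 2.0


@dataclass
class SpikeShapeParams:
    """Parameters of one class's prototypical AP waveform."""

    apt_mv: float
    amplitude_mv: float
    apd_ms: float
    rise_fall_ratio: float
    ahp_mv: float
    ahp_tau_ms: float = 20.0
    ahp_onset_ms: float = 0.15
    jitter_cv: float = 0.05

    def validate(self) -> None:
        if self.amplitude_mv <= 0:
            raise ParameterError("amplitude_mv must be positive")
        if self.apd_ms <= 0:
            raise ParameterError("apd_ms must be positive")
        if self.rise_fall_ratio <= 0:
            raise ParameterError("rise_fall_ratio must be positive")
        if self.ahp_tau_ms <= 0 or self.ahp_onset_ms <= 0:
            raise ParameterError("ahp_tau_ms and ahp_onset_ms must be positive")
        if self.ahp_mv < 0 or self.jitter_cv < 0:
            raise ParameterError("ahp_mv and jitter_cv must be non-negative")


@dataclass
class ClassSpec:
    """How many neurons and spikes to generate for one class."""

    label: str
    shape: SpikeShapeParams
    n_neurons: int = 5
    spikes_per_neuron: int = 120
    rest_mv: float = -65.0

    def validate(self) -> None:
        if self.n_neurons < 1 or self.spikes_per_neuron < 1:
            raise ParameterError("n_neurons and spikes_per_neuron must be >= 1")
        self.shape.validate()


@dataclass
class SyntheticDataset:
    """Generated traces with ground truth and a regeneration manifest."""

    traces: List[Trace]
    ground_truth_markers: List[np.ndarray]
    manifest: Dict


# Class-typical shapes: APD and AHP anchored to reported class means for
# PV/SST/Pyr; thresholds, amplitude, asymmetry and jitter are this
# package's calibration choices.
PRESET_SHAPES: Dict[str, Dict[str, SpikeShapeParams]] = {
    "paper3": {
        "PV": SpikeShapeParams(apt_mv=-40.0, amplitude_mv=65.0, apd_ms=0.70,
                               rise_fall_ratio=0.8, ahp_mv=12.45,
                               ahp_tau_ms=8.0, ahp_onset_ms=0.10),
        "SST": SpikeShapeParams(apt_mv=-44.0, amplitude_mv=65.0, apd_ms=1.18,
                                rise_fall_ratio=0.6, ahp_mv=7.23,
                                ahp_tau_ms=20.0, ahp_onset_ms=0.25),
        "Pyr": SpikeShapeParams(apt_mv=-42.0, amplitude_mv=65.0, apd_ms=1.41,
                                rise_fall_ratio=0.5, ahp_mv=3.06,
                                ahp_tau_ms=35.0, ahp_onset_ms=0.40),
    },
}
PRESET_SHAPES["allen5"] = dict(
    PRESET_SHAPES["paper3"],
    VIP=SpikeShapeParams(apt_mv=-43.0, amplitude_mv=65.0, apd_ms=0.95,
                         rise_fall_ratio=0.65, ahp_mv=9.0,
                         ahp_tau_ms=14.0, ahp_onset_ms=0.18),
    **{"5HT3a": SpikeShapeParams(apt_mv=-41.0, amplitude_mv=65.0, apd_ms=1.05,
                                 rise_fall_ratio=0.7, ahp_mv=5.5,
                                 ahp_tau_ms=17.0, ahp_onset_ms=0.22)},
)


def preset_specs(
    name: str, n_neurons: int = 5, spikes_per_neuron: int = 120
) -> List[ClassSpec]:
    """Build the ClassSpec list for a named preset."""
    if name not in PRESET_SHAPES:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(PRESET_SHAPES)}")
    return [
        ClassSpec(label=label, shape=shape, n_neurons=n_neurons,
                  spikes_per_neuron=spikes_per_neuron)
        for label, shape in PRESET_SHAPES[name].items()
    ]


def _jittered(shape: SpikeShapeParams, rng: np.random.Generator) -> SpikeShapeParams:
    cv = shape.jitter_cv
    if cv == 0:
        return shape

    def mult() -> float:
        return float(np.clip(1.0 + cv * rng.standard_normal(), 0.2, 5.0))

    return SpikeShapeParams(
        apt_mv=shape.apt_mv * mult(),
        amplitude_mv=shape.amplitude_mv * mult(),
        apd_ms=shape.apd_ms * mult(),
        rise_fall_ratio=shape.rise_fall_ratio * mult(),
        ahp_mv=shape.ahp_mv * mult(),
        ahp_tau_ms=shape.ahp_tau_ms * mult(),
        ahp_onset_ms=shape.ahp_onset_ms * mult(),
        jitter_cv=0.0,
    )


def make_spike(
    shape: SpikeShapeParams,
    fs: float = 20000.0,
    seed: Optional[int | np.random.Generator] = None,
) -> np.ndarray:
    """One AP waveform (absolute mV) spanning −1 to +2 ms around the peak.

    The peak sits at sample ``round(fs/1000)``. With ``jitter_cv > 0`` the
    shape parameters are jittered once per call using the seeded generator.
    """
    if fs < 10000:
        raise ParameterError(f"make_spike requires fs >= 10 kHz, got {fs}")
    shape.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = _jittered(shape, rng)
    hwhm_f = p.apd_ms / (1.0 + p.rise_fall_ratio)
    hwhm_r = p.rise_fall_ratio * hwhm_f
    w_r = 1.5 * hwhm_r  # quarter-cosine support per limb
    w_f = 1.5 * hwhm_f
    if w_r > _WINDOW_PRE_MS or w_f > _WINDOW_POST_MS:
        raise ParameterError(
            f"apd_ms={p.apd_ms:.3g} (ratio {p.rise_fall_ratio:.3g}) does not fit "
            f"the -{_WINDOW_PRE_MS}/+{_WINDOW_POST_MS} ms window"
        )
    n_pre = int(round(fs / 1000.0 * _WINDOW_PRE_MS))
    n_post = int(round(fs / 1000.0 * _WINDOW_POST_MS))
    s = (np.arange(n_pre + n_post) - n_pre) * 1000.0 / fs  # ms relative to peak
    v = np.full(s.size, p.apt_mv)
    rise = (s >= -w_r) & (s <= 0)
    v[rise] = p.apt_mv + p.amplitude_mv * np.cos(np.pi * (-s[rise]) / (2.0 * w_r))
    fall = (s > 0) & (s <= w_f)
    v[fall] = p.apt_mv + p.amplitude_mv * np.cos(np.pi * s[fall] / (2.0 * w_f))
    after = s > w_f
    u = s[after] - w_f
    if u.size:
        # Gaussian-ramped exponential undershoot, normalized on the window
        # grid so the trough depth is exactly ahp_mv regardless of the
        # kinetic parameters (onset sharpness and decay constant).
        shape_u = (1.0 - np.exp(-(u**2) / (2.0 * p.ahp_onset_ms**2))) * np.exp(
            -u / p.ahp_tau_ms
        )
        peak_shape = float(shape_u.max())
        if peak_shape > 0:
            v[after] = p.apt_mv - p.ahp_mv * shape_u / peak_shape
    return v


def make_trace(
    spec: ClassSpec,
    duration_s: Optional[float] = None,
    noise_sd_mv: float = 0.5,
    line_amp_mv: float = 1.0,
    line_hz: float = 50.0,
    fs: float = 20000.0,
    seed: Optional[int | np.random.Generator] = None,
    neuron_id: str = "",
    mean_isi_above_refractory_ms: float = 25.0,
) -> Tuple[Trace, np.ndarray]:
    """One neuron's trace with ``spec.spikes_per_neuron`` spikes + markers.

    Spike times follow exponential inter-spike intervals above a 10 ms
    refractory floor; ground-truth peak sample indices are returned.
    """
    spec.validate()
    n_spikes = spec.spikes_per_neuron
    if duration_s is None:
        duration_s = n_spikes * (_REFRACTORY_MS + 30.0) / 1000.0 + 0.02
    if duration_s <= 0:
        raise ParameterError(f"duration_s must be positive, got {duration_s}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    start_margin = (_WINDOW_PRE_MS + _PRE_RAMP_MS + 0.5) / 1000.0
    end_margin = (_WINDOW_POST_MS + _POST_RAMP_MS + 0.5) / 1000.0
    usable = duration_s - start_margin - end_margin
    refr = _REFRACTORY_MS / 1000.0
    if usable < (n_spikes - 1) * refr:
        raise ParameterError(
            f"{n_spikes} spikes cannot fit {duration_s:.3g} s at a "
            f"{_REFRACTORY_MS} ms refractory floor"
        )
    mean_exp = mean_isi_above_refractory_ms / 1000.0
    times = None
    for _ in range(100):
        isis = refr + rng.exponential(mean_exp, size=n_spikes)
        isis[0] = rng.exponential(mean_exp)  # no refractory before the first spike
        cand = start_margin + np.cumsum(isis)
        if cand[-1] <= duration_s - end_margin:
            times = cand
            break
    if times is None:
        raise ParameterError(
            f"could not place {n_spikes} exponential ISIs in {duration_s:.3g} s"
        )
    peaks = np.round(times * fs).astype(np.int64)

    samples = np.full(n_samples, spec.rest_mv)
    n_pre = int(round(fs / 1000.0 * _WINDOW_PRE_MS))
    n_post = int(round(fs / 1000.0 * _WINDOW_POST_MS))
    m_pre = int(round(fs / 1000.0 * _PRE_RAMP_MS))
    m_post = int(round(fs / 1000.0 * _POST_RAMP_MS))
    for t in peaks:
        wave = make_spike(spec.shape, fs=fs, seed=rng)
        samples[t - n_pre : t + n_post] = wave
        # cosine ramps tie the epoch's threshold baseline to rest
        x_up = np.arange(1, m_pre + 1) / m_pre
        samples[t - n_pre - m_pre : t - n_pre] = spec.rest_mv + (
            wave[0] - spec.rest_mv
        ) * 0.5 * (1.0 - np.cos(np.pi * x_up))
        x_dn = np.arange(1, m_post + 1) / m_post
        samples[t + n_post : t + n_post + m_post] = spec.rest_mv + (
            wave[-1] - spec.rest_mv
        ) * 0.5 * (1.0 + np.cos(np.pi * x_dn))
    phase = rng.uniform(0.0, 2.0 * np.pi)
    if line_amp_mv:
        tgrid = np.arange(n_samples) / fs
        samples = samples + line_amp_mv * np.sin(2.0 * np.pi * line_hz * tgrid + phase)
    if noise_sd_mv:
        samples = samples + rng.normal(0.0, noise_sd_mv, size=n_samples)
    trace = Trace(
        samples=samples,
        meta=TraceMetadata(fs=fs, neuron_id=neuron_id, class_label=spec.label),
    )
    return trace, peaks


def make_dataset(
    specs: List[ClassSpec],
    fs: float = 20000.0,
    seed: Optional[int] = None,
    noise_sd_mv: float = 0.5,
    line_amp_mv: float = 1.0,
    line_hz: float = 50.0,
    duration_s: Optional[float] = None,
) -> SyntheticDataset:
    """Generate every trace of a multi-class dataset, with a manifest.

    The manifest records all parameters plus the seed; regeneration from
    it (:func:`from_manifest`) is bit-identical.
    """
    if len(specs) < 2:
        raise ParameterError("a dataset needs at least 2 classes")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ParameterError(f"duplicate class labels in {labels}")
    for s in specs:
        s.validate()
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    manifest = {
        "fs": fs,
        "seed": int(seed),
        "noise_sd_mv": noise_sd_mv,
        "line_amp_mv": line_amp_mv,
        "line_hz": line_hz,
        "duration_s": duration_s,
        # calibration choices of this package, not anchored to reported
        # class-typical values
        "calibration_defaults": [
            "rest_mv", "amplitude_mv", "apt_mv", "rise_fall_ratio",
            "ahp_tau_ms", "ahp_onset_ms", "jitter_cv", "noise_sd_mv", "line_amp_mv",
        ],
        "classes": [
            {
                "label": s.label,
                "n_neurons": s.n_neurons,
                "spikes_per_neuron": s.spikes_per_neuron,
                "rest_mv": s.rest_mv,
                "shape": asdict(s.shape),
            }
            for s in specs
        ],
    }
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(sum(s.n_neurons for s in specs)))
    traces: List[Trace] = []
    markers: List[np.ndarray] = []
    for spec in specs:
        for j in range(spec.n_neurons):
            rng = np.random.default_rng(next(children))
            trace, peaks = make_trace(
                spec,
                duration_s=duration_s,
                noise_sd_mv=noise_sd_mv,
                line_amp_mv=line_amp_mv,
                line_hz=line_hz,
                fs=fs,
                seed=rng,
                neuron_id=f"{spec.label}_{j:02d}",
            )
            traces.append(trace)
            markers.append(peaks)
    return SyntheticDataset(traces=traces, ground_truth_markers=markers, manifest=manifest)


def from_manifest(manifest: Dict) -> SyntheticDataset:
    """Regenerate a dataset bit-identically from its manifest."""
    specs = [
        ClassSpec(
            label=c["label"],
            shape=SpikeShapeParams(**c["shape"]),
            n_neurons=c["n_neurons"],
            spikes_per_neuron=c["spikes_per_neuron"],
            rest_mv=c["rest_mv"],
        )
        for c in manifest["classes"]
    ]
    return make_dataset(
        specs,
        fs=manifest["fs"],
        seed=manifest["seed"],
        noise_sd_mv=manifest["noise_sd_mv"],
        line_amp_mv=manifest["line_amp_mv"],
        line_hz=manifest["line_hz"],
        duration_s=manifest["duration_s"],
    )
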