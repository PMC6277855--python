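# Methods

This note documents the models, the numerical choices, and the design
decisions behind `spiketype`, and states explicitly what the synthetic
benchmark does and does not demonstrate.

## Signal model and preprocessing

Input is a single-channel intracellular membrane-potential trace in mV at
a known sampling rate (traces below assume 20 kHz). Denoising is fixed as
notch-then-smooth:

* **Line-noise notch.** An order-3 Butterworth band-stop with edges at
  `center ± bandwidth/2` (default 47.5–52.5 Hz), applied forward and
  backward (`sosfiltfilt`, second-order sections, odd-reflection edge
  padding), so the net phase shift is zero and stop-band attenuation is
  doubled. "Order 3" is read as the order of the analog prototype; the
  resulting band-stop has 6 poles. Note the narrow band implies an
  impulse response of a few hundred ms — traces much shorter than ~1 s
  will not reach the nominal attenuation.
* **Moving average.** Centered boxcar of `L = round(0.4 ms · fs)` samples
  (8 at 20 kHz). Even windows split asymmetrically — `floor(L/2)` samples
  before the center, the remainder after — a fixed convention chosen for
  reproducibility. Edges are reflection-padded, so the output never
  leaves the input's range.

## Spike detection and epochs

A marker is the index of the maximum of each contiguous supra-threshold
excursion (plateaus resolve to the earliest sample; peaks closer than the
2 ms refractory guard keep only the larger). The threshold is
user-supplied (−20 mV default): AP peaks overshoot far above any
subthreshold activity, so an absolute threshold with an override is
transparent. Epochs are the half-open window
`[t − round(pre·fs), t + round(post·fs))` with pre = 1 ms, post = 2 ms:
exactly 60 samples at 20 kHz with the peak at offset 20. The half-open
convention is what reconciles a nominal 3 ms window with a 60-sample
epoch (an inclusive window would have 61).

## Features

**DCT coefficients.** Epochs are zero-padded at the tail (preserving the
pre-peak alignment) to 100 samples and transformed by the DCT-II. Two
normalization conventions are implemented:

* `ortho` (default): α(0)=√(1/N), α(k≥1)=√(2/N) — the orthonormal,
  energy-preserving transform;
* `literal`: α(k)=√((k+1)/N) — a diagonal reweighting emphasizing
  higher-order coefficients.

The two differ only by a per-column rescaling. Because the classifier
standardizes every column before PCA, **the choice has no effect on
classification** — both conventions give identical predictions. It does
affect scatter-based separability: trace(S_b) and trace(S_w) are
invariant under orthogonal maps and unchanged by zero-padding, so under
`ortho` the J3 of the DCT features *provably equals* the J3 of the raw
waveforms. Any reported J3 difference between DCT features and raw
epochs is therefore a statement about a non-orthonormal α; the package
computes that contrast under `literal`.

No baseline subtraction is applied before the DCT: absolute threshold
voltages are themselves class-informative.

**AP morphometry.** Seven variables per spike, all landmark crossings
located by linear interpolation between samples: APT (voltage where
dV/dt — central differences scaled by fs — first reaches 10 V/s before
the peak; the crossing itself is interpolated, since a sample-resolution
threshold voltage carries an up-to-one-sample bias straight into AHP);
APD (full width at APT + amplitude/2); AHP (APT minus the post-peak
minimum, floored at 0); RT and FT (10→90 % and 90→10 % of amplitude);
RR and FR (extreme dV/dt). Spikes with no measurable threshold or
half-width crossing are dropped and counted; an all-invalid set is an
error. The dV/dt criterion is configurable.

**PCA.** Correlation-matrix PCA: columns are z-scored by the training
mean and ddof-1 SD (constant columns get unit scale with a warning), so
the eigenvalues sum to the dimension. Retention keeps the smallest q
with cumulative explained variance ≥ 90 %; an explicit component-count
override exists because the retention rule and a fixed "keep 2" policy
are both defensible readings of common practice. Component signs follow
the largest-magnitude-loading-positive convention.

## Classifier

Training fits the standardization + PCA on the labeled training features
only, then runs fuzzy c-means (m = 2, tolerance 1e-5 on the maximum
center displacement, ≤ 300 iterations, centers initialized from seeded
sampled data points) **within each class** in PC-score space, with 2
clusters per class by default — broad interneuron classes (SST in
particular) are known to contain waveform sub-clusters. Each center is
stored tagged with its class; classification is minimum Euclidean
distance over all stored centers, ties to the earliest-stored center.
Per-class clustering was chosen over global clustering plus majority
labeling because it is deterministic in how centers acquire labels.
Neuron-level calls are majority votes over the neuron's spikes, ties
resolved by the smaller mean winning distance.

## Evaluation

Stratified spike-level k-fold CV (default k = 10, seeded, shuffled);
standardization, PCA and FCM are refit inside each fold by default.
Two switches acknowledge methodological alternatives: `pca_global` fits
PCA once on all data (the laxer reading), and `group_by_neuron` performs
leave-neurons-out splitting, since spike-level splitting lets spikes of
one neuron appear on both sides of a fold — a leakage the default
faithfully reproduces and the switch removes. Metrics are one-vs-rest
precision, recall and accuracy per class, averaged over folds with SEM;
overall values are unweighted class means. An undefined precision (class
never predicted in a fold) is reported as missing and excluded from the
macro mean rather than coerced to 0. Between-class scatter uses the
class-size-weighted form S_b = Σᵢ nᵢ(mᵢ−m)(mᵢ−m)ᵀ. Classifier
comparisons: Cochran's Q across ≥ 3 classifiers, continuity-corrected
McNemar χ² = (|b−c|−1)²/(b+c) for pairs, Bonferroni adjustment
p·m capped at 1.

## Synthetic data generator

Each class is a prototypical waveform plus per-spike variability:

* **Rise/fall limbs** are quarter-cosine lobes `A·cos(πs/2w)`. A lobe of
  support w has its half-maximum at 2w/3, so supports follow directly
  from the requested duration at half maximum (`apd_ms`) and rise/fall
  asymmetry. Compact support (1.5× the half-width at half maximum per
  limb) guarantees even the broadest pyramidal-like spike repolarizes
  inside the +2 ms window with room for the AHP trough; heavier-tailed
  limbs (e.g. half-Gaussians, support ≈ 3.4× their half-width) do not,
  which makes the AHP depth uncalibratable within the epoch.
* **AHP**: a Gaussian-ramped exponential undershoot below threshold,
  normalized on the sampled window so the trough depth is exactly
  `ahp_mv`. Its kinetics — onset sharpness and decay constant — are
  class-conditioned (PV fast and sharp, Pyr slow, mirroring the
  fAHP/mAHP contrast) and deliberately invisible to the seven
  morphometric scalars, so that waveforms carry class information beyond
  those parameters, as real spike waveforms do.
* **Variability**: independent multiplicative jitter (CV 0.05 by
  default) on each shape parameter per spike.
* **Traces**: spikes placed by exponential inter-spike intervals above a
  10 ms refractory floor; short cosine ramps tie each epoch's threshold
  baseline to the −65 mV resting potential so the trace is step-free;
  additive white Gaussian noise (0.5 mV SD) and a 1 mV, 50 Hz sinusoid
  with random phase.

The `paper3` preset anchors APD (0.70 / 1.18 / 1.41 ms) and AHP depth
(12.45 / 7.23 / 3.06 mV) to reported class-typical values for PV / SST /
Pyr; thresholds (−40 / −44 / −42 mV), amplitude (65 mV), asymmetry,
kinetics, jitter and noise levels are this package's own calibration,
flagged as such in the manifest. `allen5` adds VIP and 5HT3a with
interpolated shapes — synthetic stand-ins, not derived from any recorded
dataset. Everything is reproducible: a dataset's manifest regenerates it
bit-identically.

Problem sizes: the default study is 3 classes × 5 neurons × ~100 spikes
(≈1500 spikes, ~4 s of trace per neuron), which the full double-pipeline
evaluation completes in a few seconds.

## What the synthetic benchmark shows — and does not

Passing the closed-loop tests shows the pipeline recovers known
generative structure: exact detection on clean traces, shape measurement
within 2 % of requested values at zero jitter, ≥ 90 % cross-validated
accuracy at default noise, and a literal-DCT J3 above the raw-waveform
J3. It does **not** show that DCT features beat the seven morphometric
parameters the way they do on recorded data: in the generator, class
variability is driven by jitter on the very parameters the morphometry
measures, and the morphometric measurements reject the small additive
noise almost perfectly, so the AP-shape pipeline is near-optimal here
(≈97 % vs ≈96 % for DCT). On recorded traces the ordering reverses
because real waveform variation is not spanned by seven scalars and
their measurement is far noisier. The generator narrows this gap through
class-conditioned AHP kinetics but, by design, is not tuned until the
ordering flips.

Other known limitations: no biophysical (conductance-based) dynamics, no
overlapping spikes, no drift or synaptic bombardment, white rather than
1/f noise, and single-channel input only.
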