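# Methods

## The recognition problem

A lower-limb exoskeleton driven by surface EMG needs the current gait
subphase — initial stance, midstance, terminal stance, initial swing,
terminal swing — decoded continuously from a handful of thigh-muscle
channels. The study design this package reproduces asks how robust that
decoding is to the *style* in which a 20%-of-body-weight load is carried:
backpack (BP, symmetric), cross-shoulder strap (CS) or straight-shoulder
strap (SS), each at 3, 5 and 7 km/h. The full design is 15 subjects × 50
gait cycles × 3 styles × 3 speeds = 6750 cycles in 135 trials.

## Synthetic signal model

No public recording of this design exists, so the package generates its own
data and treats the generator as a first-class, tested component.

**Timing.** Cycle durations are Gaussian around speed-dependent means
(1.30 / 1.05 / 0.85 s at 3 / 5 / 7 km/h) with a 3% relative SD. The five
subphases sit at fractional offsets 0 / 0.12 / 0.31 / 0.62 / 0.81 / 1.0 of
the cycle — standard gait-phase timing with toe-off at 62% — each interior
boundary jittered (SD 0.01 of the cycle) and re-sorted so every cycle tiles
into five strictly increasing half-open intervals.

**Activation.** Each muscle follows a phase-locked envelope: a 5 × 4 table
of mean activation levels in [0, 1] (stance muscles — tensor fasciae latae,
semitendinosus — peak in stance subphases; swing muscles — adductor longus,
vastus medialis — in swing), scaled by the subject's per-muscle baseline
amplitude (~240–310 µV), a speed drive (0.85 / 1.0 / 1.2) and the load
style. Piecewise-constant levels are smoothed by a Hann kernel of ±30 ms.
Cycle-to-cycle physiological variability enters as a multiplicative
per-cycle, per-muscle gain with SD 0.12.

**Load styles.** Styles act through three knobs per style: an amplitude
scale, an asymmetry factor multiplying the loaded-side channels (the strap
side is unrecorded in the montage, so which channels are "loaded" is a
config choice, default channels 1–2), and a variance-inflation factor ≥ 1
multiplying the cycle-gain variance. Defaults are BP (1.00, 1.00, 1.0),
SS (1.25, 1.30, 1.4), CS (1.50, 1.60, 2.0). These magnitudes were
calibrated once so the generator behaves like the study it emulates:
classifiers can learn the phases well within a style, separability orders
BP > SS > CS, and training on one style transfers poorly to another. They
are configuration, not claims about physiology.

**Carrier and noise.** The raw signal is envelope × unit-variance Gaussian
noise band-limited to 20–400 Hz (4th-order Butterworth, forward–backward),
plus wideband Gaussian baseline noise (SD 3 µV) and a 50 Hz mains sinusoid
(20 µV default) so the notch filter has something to remove. Amplitudes
clip at the ±1600 µV acquisition range. All randomness derives from integer
seeds via `numpy.random.SeedSequence`; a master seed spawns per-subject and
per-trial seeds, so any trial regenerates independently and bit-identically.

**What the generator does not emulate.** Motor-unit physiology, fatigue
drift, electrode lift or repositioning, inter-session variability,
crosstalk, kinematic coupling between channels, and bilateral recording.
Passing tests therefore show that the *pipeline* behaves as specified and
that the load-style logic produces the expected orderings on data with this
covariance structure — not that the same accuracies would be reached on
physiological recordings.

## Preprocessing

Filtering is a zero-phase (forward–backward) 4th-order Butterworth bandpass
at 10–400 Hz followed by an IIR notch at 50 Hz (quality factor 30).
Zero-phase filtering is chosen so the gait-event annotations stay aligned
with the filtered trace. Labels follow the half-open convention
[start, end): a sample exactly on a boundary belongs to the later subphase.
Windowing takes "30 ms windows overlapped by 10 ms" literally: step =
20 ms = 40 samples, window = 60 samples; the alternative reading (step =
10 ms) is available through the `overlap_ms` argument. A window's label is
the majority of its per-sample labels, ties broken toward the earlier
phase; windows touching unlabelled samples are dropped.

## Image formation

The greyscale mapping is per-channel min–max scaling with bounds fitted on
the training split only, values clipped to [0, 1]; a degenerate channel
(max = min) maps to 0.5. Continuous values are kept (no 8-bit quantization)
to preserve amplitude resolution; a global-scale mode and an 8-bit mode
exist as config flags for sensitivity analysis. Fitting on training data
only is part of the evaluation contract — test windows may clip but never
leak into the scale.

## CNN

Architecture and constants are fixed: 4 × 60 input; C2 = 7 spatial filters
(4 × 1) giving 7 × 60 maps; C3 = 6 temporal filters (1 × 6) applied with
stride 6 (non-overlapping, which is what yields 1 × 10 maps) giving 42
maps; F4 = 110 sigmoid units over the flattened 420 features; O5 = 5
sigmoid units, argmax decision with ties to the lower phase index. C2/C3
use f(u) = 1.7159·tanh(2u/3). Gradients are derived and implemented by
hand and verified against central finite differences (< 1e-4 relative)
at initialization and after training steps.

Choices the architecture's description leaves open, and what this package
does:

* **Loss** — mean squared error against one-hot targets by default
  (consistent with sigmoid outputs); per-unit cross-entropy by config.
* **Initialization** — uniform on ±1/√N_in (N_in = fan-in of the receiving
  neuron); the literal ±1/N_in reading is a config switch.
* **Learning rates** — σ = 2ψ/(N_sh·√N_in) for the shared-weight
  convolutional layers (N_sh = 60 for C2, 10 for C3) and σ = ψ/√N_in for
  the fully connected layers. ψ is a free constant, default 0.1.
* **Iterations** — an iteration is one parameter update; the default
  budget is 10⁴ full-batch updates. A mini-batch mode (optionally
  phase-balanced sampling) counts one update per iteration.
* **Divergence** — a non-finite loss raises an error naming the iteration.

**Experiment-driver settings.** The library defaults above describe the
canonical configuration. For the evaluation experiments the driver uses a
configuration selected once by validation accuracy: cross-entropy loss,
ψ = 5, phase-balanced mini-batches of 30, single-precision arithmetic, and
4000–6000 iterations. With full-batch MSE at ψ = 0.1 the loss sits in a
long plateau (the network must synthesize variance detectors from
near-linear features before phase information flows); balanced mini-batch
cross-entropy escapes that plateau roughly an order of magnitude sooner at
equal cost per update, which is what makes the multi-seed experiments
feasible at desk scale.

## Baselines

iEMG is implemented as the mean absolute value (1/N)Σ|V_k| — note the 1/N
factor; the classical integrated-EMG definition omits it, which is
scale-equivalent at fixed N = 60. RMS is √((1/N)ΣV²). Features are
[RMS, iEMG] per channel in channel order (8 values). The SVM is an RBF
pipeline (standardization → SVC) with C ∈ {0.1, 1, 10, 100} and
γ ∈ {0.01, 0.1, 1, 10} chosen by 5-fold cross-validation, one-vs-one
multiclass. The BPNN is 8 → 20 → 5 with logistic activations and an argmax
decision; a literal single-output head (regressing the phase index,
rounded) is available by config since a one-node output cannot natively
express five classes.

## Evaluation protocol

Splits are 60/20/20 train/validation/test, stratified by phase, per window
(a per-cycle grouped split is the recommended alternative when temporal
leakage matters; window-level splitting matches the protocol being
reproduced). Per-phase accuracy is recall on the test windows; the trial
accuracy is the mean of the five. Cross-style matrices train on one style's
training split and test on its own test split (diagonal) or the foreign
style's full pool (off-diagonal — none of it was trained on). The
mixed-style experiment pools the three styles' test splits and trains on
each of the 7 non-empty style subsets. Every report retains its raw
prediction log so all summaries can be recomputed.

## Problem sizes

The reproduction script and end-to-end checks run at a desk scale chosen once: 2 subjects ×
10 cycles at 5 km/h for the style experiments (window pools capped at 600
per style, phase-stratified), aggregated over 5 master seeds; the
combinatorics checks use the full 15 × 50 × 3 × 3 design with signals
elided (events only). The separability sanity check uses a dedicated
low-noise configuration — orthogonal per-phase activation patterns, gain
SD 0.04, 10 ms transitions, 1 µV noise — and keeps only label-pure windows,
because windows straddling a subphase boundary have intrinsically ambiguous
majority labels.

## Known limitations

* Absolute accuracies on synthetic data are not comparable to recordings
  of real muscles; only the qualitative orderings (intra > inter; more
  training styles → better pooled accuracy; BP easiest, CS hardest) are
  meaningful, and those are what the tests assert.
* The CNN learns amplitude structure from greyscale images much more slowly
  than the feature-based baselines learn from explicit RMS/iEMG features;
  on this generator's data the SVM is the stronger classifier at equal
  compute budget.
* Statistical hypothesis testing (ANOVA, post hoc contrasts) is out of
  scope; reports serialize to tidy CSV/JSON for external analysis.
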