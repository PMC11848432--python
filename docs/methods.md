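# Methods

`somnoweave` is a tested re-implementation of a sleep-condition recognition
pipeline for collar-mounted six-channel strain-sensor arrays. Because the
garment's recorded dataset is external, the package ships a synthetic signal
generator that reproduces the statistical structure of those recordings, and
everything downstream — preprocessing, the SleepNet classifier, structured
pruning, few-shot transfer, and the evaluation suite — is exercised against
that generator. This note documents the models, the parameters that matter,
the numerical choices, and what the synthetic results do and do not show.

## Signal model

The sensing site is the extrinsic laryngeal muscle region: vibrations from
the velum, oropharynx, tongue and epiglottis are transmitted to the neck and
picked up as strain by a printed piezoresistive array. Six sleep states are
modeled — nasal breath, mouth breath, snoring, bruxism, central sleep apnea
(CSA) and obstructive sleep apnea (OSA) — all with spectral energy below
10 Hz, sampled at `fs = 100` Hz.

Each state's waveform kernel is a parametric sketch of its phenomenology,
not a physiological model:

- **Breath carrier** (all states): a quasi-periodic oscillation at
  `breath_rate_hz` (default 0.25 Hz, resting range 0.15–0.4) with harmonic
  shaping, inhale/exhale skew via phase warping, slow amplitude modulation,
  and band-limited phase noise so the fundamental stays a sharp spectral
  line while cycle lengths jitter.
- **Nasal vs mouth breathing** differ in harmonic weights
  (`nasal_harmonics`, `mouth_harmonics`), waveform skew
  (`*_asymmetry`) and rate (`mouth_rate_scale = 0.85`).
- **Snoring**: the carrier plus a 4–9 Hz band-noise oscillation gated to the
  inspiratory half of each cycle, with slow loudness variation
  (`snore_burst_gain = 1.6`).
- **Bruxism**: a faint carrier plus sparse Poisson-scheduled grinding bursts
  (`bruxism_event_rate_per_min = 10`, duration ≈ 0.8 s, `burst_gain = 3`),
  each a Hann-windowed 7 Hz oscillation with 5–9 Hz roughness.
- **CSA**: the carrier multiplied by an envelope with scheduled silent
  pauses (`csa_pause_s = 8`, `csa_pause_fraction = 0.5`, 2% residual
  microvibration, 0.3 s ramps). Pauses are dense enough that every 10-s
  epoch of a CSA session overlaps at least one pause, so every epoch's label
  is supported by its content.
- **OSA**: alternating obstructed segments (suppressed carrier plus an
  erratic 0.8–3 Hz effort oscillation, `osa_effort_gain = 1.3`) and recovery
  breaths (carrier × 1.6), with `osa_obstruction_duty = 0.7` over a 20-s
  cycle — again so that no 10-s epoch consists of recovery breathing alone.

Amplitudes are in strain units (default `breath_amplitude = 0.005`, i.e.
0.5% strain). The transduction model is the piezoresistive gauge relation
ΔR/R₀ = GF·ε with `gauge_factor = 100`; with a constant 1 V supply the
readout current is I = V / (R₀(1 + ΔR/R₀)), monotone decreasing in strain.
Records store ΔR/R₀ by default (a declared unit flag) because per-epoch
Z-scoring downstream makes the affine choice immaterial.

**Array projection.** The six-channel crossbar is reduced to a per-channel
scalar gain (defaults spread over 0.85–1.15) plus independent Gaussian
sensor noise (`channel_noise_sd = 0.04` in ΔR/R₀ units). This reproduces
the garment's measured structure: any two channels correlate at r > 0.9
while their intensities differ with wearing position, which is what makes
strongest-channel selection a positioning-free strategy. With zero noise the
correlation is exactly 1 by construction; r decreases monotonically in the
noise level.

**Turning artifacts.** A nocturnal turning adds a Gaussian pulse
(width 1.5 s) plus an exponential-approach baseline drift
(30% of the pulse magnitude, τ = 5 s) to all channels. With the
strain-isolation flag the pulse is attenuated ×0.2 and the drift ×0.1 —
invented attenuation factors standing in for the garment's qualitative
before/after behavior, exposed in `SimConfig`.

**Per-subject domain shift.** Each simulated wearer perturbs channel gains
(±20%), breathing rate (±15%) and noise (±30%), seeded, which creates the
transfer gap the few-shot experiments need.

**Dataset assembly.** `simulate_dataset` sizes each record so that 10-s
windows at 50% overlap yield exactly the requested per-class epoch counts;
the shipped default counts are 728/701/262/180/102/146
(nasal/mouth/snore/bruxism/CSA/OSA), 2,119 epochs total, spread over five
subjects.

## Preprocessing

- **Segmentation**: 10-s windows (1000 samples), 50% overlap; a window
  keeps a label only when a single annotation covers it entirely, otherwise
  it is dropped. Window count per fully covered span of `T` seconds is
  `floor((T − W)/S) + 1` (property-tested against brute-force enumeration).
- **Strongest channel**: argmax of mean power in the 0.05–10 Hz band after
  mean removal, per window by default (a per-record majority vote is
  available); ties break to the lowest index; an all-constant window logs a
  warning and falls back to channel 0.
- **Z-score**: per-epoch standardization with a near-constant guard
  (sd < 1e-8 maps to zeros).
- **Splits**: proportional random 90/10 train/validation per class, seeded.
  Because adjacent 50%-overlap epochs share samples, the default epoch-level
  split can leak between train and validation; a grouped mode assigns whole
  source records to one side, and `hold_out_records` builds an isolated test
  split that never shares a record with train/val.

## SleepNet

Input is one 1000-sample normalized epoch. The path is:

1. **Patch projection**: strided `Conv1d(1 → d_model, kernel 21, stride
   10)`, giving 100 tokens of width 32. This is the encoder's input
   projection; it also sets the sequence length the recurrent and attention
   stages operate on.
2. **Residual BiLSTM positional encoder**: `x = proj + W·BiLSTM(proj)`
   (hidden 32 per direction). Zeroing the BiLSTM path reduces the encoder to
   the projection exactly (a tested contract).
3. **Self-attention**: two post-norm transformer blocks (4 heads,
   feed-forward 64, dropout 0.1).
4. **1-D ResNet**: three blocks with channels (64, 128, 128), kernel 7,
   strides (2, 2, 1); each block is conv-BN-ReLU-conv-BN with a 1×1
   projection shortcut (a projection even when shapes match, so channel
   pruning can rewire every block uniformly).
5. **Head**: global average pooling (the penultimate embedding used for
   t-SNE and linear probes) and an affine 6-way softmax.

The network and its training loop are implemented on a compact NumPy kernel
(`somnoweave.nn`): every layer carries an explicit backward pass, validated
end-to-end against central finite differences in float64; training runs in
float32. The optimizer is Adam (default lr 3e-3, batch 64) with early
stopping on validation accuracy; all initialization and batch order is
seeded. An intentional property of this stack: the same backward machinery
provides input gradients, so SmoothGrad needs no separate autodiff.

**Profiling convention.** FLOPs = 2 × multiply-accumulates of one forward
pass (projections, LSTM gates, attention products, convolutions, head);
normalizations and activations are not counted. Parameter counts are
trainable scalars only. The shipped default profiles to ≈0.51 M parameters
and ≈0.035 GFLOPs at input length 1000; after 50% pruning ≈0.16 M and
≈0.017 GFLOPs — comfortably inside the sub-5 M/sub-0.5 GFLOPs budget for
edge deployment.

**Structured pruning.** Convolution output channels ("nodes") of the ResNet
stack are ranked per layer by filter L1 norm; the lowest `fraction`
(default 0.5, per layer rather than global) are removed with
dependency-consistent rewiring: conv1's output set, the block output set
(conv2 + shortcut, ranked by summed L1), the next block's inputs, and the
classifier head all follow. Pruning 50% cuts profiled FLOPs by ≈53%, and a
short retraining pass restores accuracy. Fraction 0 is an exact identity.

## Training protocols

- **Hyperparameter search**: independent seeded trials over a declared
  space (learning rate log-uniform, LSTM width, attention FFN width, ResNet
  widths); a robustness summary reports the fraction of trials above an
  accuracy threshold. The suite runs a reduced analogue (6 trials, 360
  epochs) of the robustness claim.
- **Few-shot transfer**: a new synthetic wearer (gain/rate/noise shift)
  supplies 15 epochs per class for adaptation. The pretrained model is
  fine-tuned on all layers at 0.1× the base learning rate (head-only mode
  available); the control trains an identically configured fresh model on
  the same shots; both are evaluated on the remaining target epochs. A
  leakage guard rejects target subjects present in the pretraining
  manifest, and shot sets that cover the whole target set are flagged as
  resubstitution. The direction (fine-tuned > scratch) is asserted over five
  paired seeds with a one-sided sign test; a 270-epoch target test set keeps
  paired comparisons tie-free at this scale.

## Evaluation artifacts

- Confusion matrix (rows true, columns predicted; argmax with ties to the
  lowest index), per-class and overall accuracy.
- One-vs-rest ROC per class using the class probability as score; AUC by
  the trapezoidal rule over the full threshold sweep, checked against a
  Mann–Whitney pair-counting oracle; macro and micro averages both
  reported; a class absent from the evaluation set gets an undefined AUC.
- **SmoothGrad**: mean input gradient of the target-class logit over `n`
  noisy copies (σ defaults to 0.1× the input sd); σ = 0, n = 1 collapses
  exactly to the plain gradient.
- **t-SNE**: seeded 2-D embedding; the silhouette score by class is the
  quantitative proxy for visual cluster separation when comparing model
  features with raw epochs.

## Chance-level control

The permuted-label control is evaluated on a class-balanced subset: with
balanced true labels any label-independent predictor has expected accuracy
exactly 1/6, so the control band (1/6 ± 5 points) tests what it should.
On the imbalanced full dataset a majority-class collapse alone would sit at
≈34% and the control would be uninterpretable.

## Problem sizes and determinism

The test suite trains the full model once on the complete 2,119-epoch
default dataset (12 epochs, early stopping) and reuses it across the
learnability, transfer, saliency and embedding checks; search and transfer
mechanics run on reduced datasets and widths. All randomness flows from
explicit seeds through named substreams (`somnoweave._seeding`), so reruns
with the same configuration reproduce metrics byte-identically.

## What passing tests show — and do not

The synthetic generator reproduces the *statistical skeleton* of garment
recordings: band-limited quasi-periodic signatures, strongly correlated
channels with positional gain differences, exact class counts, seeded
subject heterogeneity, turning artifacts. It does not reproduce real
airflow acoustics, electrochemical sensor drift, posture-dependent
non-stationarity, inter-night variability, or the labeling noise of human
annotation. Accuracies on synthetic data (≈99% held-out here) therefore
validate the pipeline's correctness and the architecture's capacity, not
clinical performance; the printed real-data accuracies of the garment study
are not reproducible from simulation and are deliberately not acceptance
surface. Known further limitations: the crossbar circuit is reduced to
scalar gains (no crosstalk), artifact attenuation factors are invented
defaults, and pruning importance is filter L1 only (pluggable).
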