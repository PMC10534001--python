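# Methods

`ppgdx` implements two parallel pipelines for screening systemic
sclerosis (SSc) from multi-site photoplethysmography (PPG) recorded
under a dynamic 3-phase protocol, plus the synthetic cohort generator
that stands in for the (unavailable) clinical recordings.

## The measurement model

A recording is 20 minutes of simultaneous PPG from six symmetrical
sites (right/left earlobe, index-finger pad, great-toe pad), sampled at
`fs` (2000 Hz clinically; 200 Hz is the synthetic default), AC-coupled
to 0.5–20 Hz by the amplifiers. The protocol is: 10 min supine baseline;
5 min left-arm cuff occlusion at 300 mmHg, which abolishes the
left-finger pulse; 5 min post-release reactive-hyperaemia ("flush")
monitoring. The only preprocessing is division of each channel by its
amplifier gain; quality control flags electronically clipped traces
(fraction of samples at the signal extremes above 2% in any 10-s span).

## Image branch

Each gain-normalised channel is cut into consecutive, non-overlapping
30-s windows (trailing partial windows dropped, so every image has
identical time support). Each window is transformed with an analytic
generalized Morse wavelet CWT and converted to a percent-energy
scalogram:

    S = |coef|²,    Scalogram = 100 · S / ΣS,

so every non-degenerate scalogram sums to exactly 100 and is invariant
to positive rescaling of the input — the images encode waveform *shape*
and relative energy distribution, not absolute amplitude.

CWT details: the Morse wavelet is defined in the frequency domain,
Ψ(ω) ∝ ω^β exp(−ω^γ) for ω > 0, with symmetry γ = 3 and
time-bandwidth P² = βγ = 60 (the common analytic default), peak-
normalised to 2. Scales are log-spaced at 12 voices per octave from
0.3 Hz to min(24, 0.98·fs/2) Hz; the transform is an FFT filter bank
with zero padding past four time-SDs of the slowest wavelet, and the
filter bank is cached per window geometry. The frequency axis is kept
on its native logarithmic spacing.

Rendering: rows are cropped to 0–20 Hz, min–max scaled *per image*,
mapped through a fixed 256-entry perceptually uniform colormap
(viridis; brighter = more energy), and bicubically resized to
224×224×3 RGB — the input contract of the ImageNet-family backbones.
Identically zero windows are excluded with a warning rather than
emitting NaN images.

The default backbone, `tiny_test_cnn`, is a from-scratch NumPy network
sized so a full 10-fold study trains in minutes on one CPU: a 14×14
average-pool stem (224→16 px), per-pixel input standardisation fitted
on the training set only (a cheap conditioning stage in place of batch
normalisation — without it the published learning rate needs ~4× more
epochs to converge), three 3×3 conv blocks (8/16/32 filters, ReLU, 2×2
max pool after the first two), global average pooling and a softmax
head (~6k parameters). Training is plain minibatch SGD: learning rate
0.005, momentum 0.9, cross-entropy loss, data split into 10
minibatches per epoch, 10 epochs by default (the epoch count is a
package choice; it is exposed in `TrainConfig`). Training is exactly
reproducible from the seed. `googlenet` / `efficientnet_b0` are
registered as optional plug-ins behind the `torch` extra, with the
final classification layer replaced by a 2-class head; the value of
the pipeline does not depend on the pretrained weights.

Participant-level classification takes the majority class of a
participant's image predictions. Exact ties go to SSc — the
sensitivity-preserving direction for a screening test, where missing a
patient is the costlier error.

## Feature branch

Each gain-normalised channel of the *full* recording (not the 30-s
windows) is decomposed with a 10-level Daubechies-4 DWT in
periodization mode. The signal is first truncated to the largest
multiple of 2^10 samples (≤0.5 s lost at 2000 Hz), which makes the
decomposition exactly orthogonal: coefficient counts halve per level
and Parseval's identity holds to machine precision. Detail level j
spans (fs/2^(j+1), fs/2^j); at 2000 Hz the retained bands are d6
(15.63–31.25 Hz) through d10 (0.98–1.95 Hz) plus the level-10
approximation (0–0.98 Hz). Note the approximation band is 0–0.98 Hz,
not 0.49–0.98 Hz: a level-10 approximation reaches down to DC. Band
edges always follow the actual sampling rate, so at the 200 Hz
synthetic default the same band names cover 0–3.125 Hz.

Per band, four features: energy Σx²; Shannon entropy (bits) of the
normalised squared-coefficient distribution p_i = x_i²/Σx² (the
textbook Σx·log(1/x) form requires positive, unit-sum inputs; the
`unnormalized` −Σx²log₂x² convention is available as a switch); mean
absolute value, read literally as |mean(x)| (switchable to mean(|x|));
and population skewness E[(x−µ)³]/σ³, defined as 0 with a warning when
σ = 0. That is 6 channels × 6 bands × 4 = 144 named features per
participant.

Features are z-scored with statistics from the training folds only,
then classified with (a) pooled-covariance LDA with light diagonal
loading (scikit-learn `lsqr` solver, shrinkage 1e-4 — necessary since
144 features exceed the participant count) and (b) KNN with K = 9,
Euclidean distance.

## Cross-validation and evaluation

Folds are drawn over participants, never windows: within each class
participants are shuffled by the seed and dealt round-robin with a
running counter, bounding per-fold positive counts and fold sizes to
±1. One serialised plan (`folds.json`) is shared by both branches so
they are compared on identical partitions; the CV driver asserts
train/test participant disjointness at runtime and that every item is
predicted exactly once.

Per-fold confusion matrices are summed into one combined matrix
(SSc positive). Accuracy, sensitivity and specificity are percentages
with exact Clopper–Pearson 95% CIs (beta-quantile inversion of the
binomial tails; coverage is conservative, ≥95% for every cell of the
tested p×n grid). Printed reports round half-up to 1 decimal. The
crosshair export transforms specificity to false-positive rate
(100 − specificity) with CI endpoints swapped.

## Synthetic cohort generator

The generator defines the study conditions for every test; it emulates
the *statistical structure* of cuff-occlusion PPG, not beat-level
physiology:

* **Beat model** — each beat is a systolic Gaussian (centre 0.25 T,
  width 0.09 T for period T) plus a dicrotic bump (0.35× amplitude,
  centre 0.55 T, width 0.14 T); beat-to-beat interval jitter 3% (CV).
  The train is band-passed to 0.5–20 Hz, emulating the AC-coupled
  amplifiers. The waveform shape is a stand-in, not a morphological
  claim.
* **Phase envelope** — closed form: ≈1 during baseline with a slow
  sinusoidal vasomotor drift (amplitude 0.02, period 300 s); on
  occluded channels an exponential collapse (τ = 5 s) after cuff
  inflation, a jump to `flush_overshoot` at release, and exponential
  relaxation to 1 with time constant `flush_tau`.
* **Phenotypes** (literature-anchored defaults): Control pulse
  amplitude 56 ± 19 a.u., flush overshoot ~1.8 (τ ≈ 15 s), homogeneous
  fingers (CV 5%); SSc amplitude 24 ± 24 a.u. truncated at 0,
  attenuated flush (overshoot ≤ 1, τ ≈ 45 s), heterogeneous fingers
  (CV 35%). Ear/toe sites scale amplitude by 0.6/0.8. Heart rate
  uniform 0.9–1.5 Hz in both classes, so rate is not a class cue.
* **Noise** — additive Gaussian, low-passed at 20 Hz, SD 1.0 a.u.
  (≈2% of the Control-mean amplitude). Instrument noise is
  amplitude-independent, so low-perfusion (SSc) recordings have
  a genuinely lower SNR; this is the main class cue that survives the
  per-image energy normalisation of the scalogram.
* **Gains** — per-channel amplifier gains log-uniform in [0.5, 2],
  recorded in the manifest, so gain normalisation is exercised.
* A `strongly_separated` phenotype preset (amplitudes 12 ± 4 vs
  60 ± 8 a.u., overshoot 0.7 vs 2.0) is used for end-to-end acceptance
  runs, where the question is whether the pipeline machinery — not the
  phenotype — limits performance.

Everything is reproducible from a single integer seed; the manifest
records every sampled parameter.

**What passing tests do and do not show.** The generator produces
band-limited, noise-floored, envelope-modulated pulse trains; it does
not model beat morphology changes, motion artifacts, probe-contact
loss, arrhythmia, or vasomotor waves beyond a deterministic drift.
End-to-end accuracy on synthetic cohorts therefore validates the
pipeline's plumbing (windowing, scalogram geometry, leakage-free CV,
vote aggregation) and its sensitivity to amplitude/SNR/flush phenotype
differences — it is a sanity floor, not evidence about clinical
performance.

## Numerical choices and problem sizes

* Desk-scale studies run at fs = 200 Hz, 35 participants
  (10 SSc / 25 Control), giving 240 images per participant (8,400
  total) — a deliberately reduced replica of the clinical geometry
  (71 participants, 16,188 images at 2000 Hz).
* The CWT filter bank spans ~76 log-spaced frequencies; all-zero
  windows are excluded; per-image min–max colour scaling means a
  constant scalogram renders as the colormap floor.
* Fold assignment, CNN initialisation/shuffling and cohort sampling
  use independent small-offset seeds derived from the study seed.
* Published-table arithmetic: the image-level specificity implied by
  the printed combined confusion matrix is 86.95%, which half-up
  rounds to 87.0 while the published table prints 86.9; the package
  reports unrounded values and tests assert agreement to one unit in
  the printed last digit.

## Known limitations

* The tiny CNN is an optimisation-friendly stand-in; absolute
  accuracies are not comparable to pretrained ImageNet backbones.
* DWT band *names* (d6…ap) are fixed by the method while their Hz
  ranges follow fs, so at 200 Hz the feature bands sit below the
  clinical 0.5–31 Hz selection rationale.
* The majority-vote tie rule (→ SSc) matters only for even image
  counts and exact ties, but it is load-bearing for reproducibility.
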