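# Methods

## Problem and model

The pipeline classifies participants as AD or control from the acoustics of
twelve short spoken answers recorded during a cognitive screening
interview. The working hypothesis is purely non-verbal: AD speech is slower,
more hesitant, carries elongated vowels and longer response latencies, and
sometimes no response at all. The classifier never sees audio directly; it
sees one 312 × 599 composite image per participant in which each of twelve
fixed question bands (26 rows each) encodes the cepstral trajectory of one
answer.

## Synthetic cohorts

Real screening recordings are private, so cohorts are synthesized. A
response is a sequence of 2–4 syllable-like bursts: the first five harmonics
of a per-syllable fundamental under a Hann envelope plus weak breath noise,
separated by gaps, preceded by a response latency, optionally interrupted by
exponentially distributed pauses. A class is a `SpeechProfile`:

| knob | control | AD | meaning |
|---|---|---|---|
| tempo_factor | 1.0 | 0.6 | syllable-rate multiplier (slows both bursts and gaps) |
| pause_prob | 0.05 | 0.5 | chance of a pause at each inter-syllable gap |
| pause_dur_mean (s) | 0.15 | 0.40 | mean pause length |
| latency_mean (s) | 0.15 | 0.50 | silence before the first syllable |
| vowel_elong | 1.0 | 1.5 | syllable-nucleus stretching |
| no_response_prob | 0.0 | 0.20 | chance of a fully silent (unanswered) item |
| f0_mean (Hz) / f0_jitter | 180 / 0.02 | 170 / 0.06 | voice pitch and its instability |

Participant profiles jitter the class means (lognormal on positive knobs,
clipped normal on probabilities, relative SD 0.10). Control answers complete
within 1–2 s, matching the interview setting the generator emulates; clips
are capped at 3 s keeping the head. These effect sizes are calibration
choices — a clearly separated but not caricatured cohort — not estimates of
any clinical population; `null_effect()` gives both classes the control
profile for calibration checks. The generator does **not** emulate phoneme
inventories, coarticulation, channel/microphone variation, background noise,
or any language-specific prosody, so a classifier that succeeds here has
only been shown to read gross spectro-temporal structure (silence layout,
tempo, spectral slope), not to diagnose patients.

Synthesis is mono (features are computed on mono regardless); an
`as_stereo` helper duplicates channels where the two-channel recording
format matters. Non-response is a `responded=False` flag plus a silent
file; standardization regenerates the 3 s of digital zeros from the flag
alone, so the class cue is well defined even if a source file contains
noise.

## Standardization

Every clip becomes exactly 132,300 samples at 44.1 kHz: right-padding with
digital zeros (the answer is front-loaded at onset, so padding goes after
it), head-keeping truncation, zeros for non-responses. No resampling is
performed — a wrong input rate is an error, since silent resampling would
invalidate the framing arithmetic below.

## Feature images

Framing uses 25 ms windows (0.025 × 44,100 = 1102.5, rounded half-up to
1103 samples) hopped by 441 samples, giving 1 + ⌊(132,300 − 1103)/441⌋ =
298 frames. Per frame: pre-emphasis 0.97, Hamming window, 2048-point FFT
(next power of two above the window), power spectrum, a 26-filter
triangular mel bank over 0–22,050 Hz, log with a 1e-10 floor, orthonormal
DCT-II, coefficients 0–12 kept. Deltas are the local linear-regression
slope over a 9-frame window (half-width 4) with edge replication, so a
silent clip has constant cepstra and exactly zero deltas. These cepstral
conventions (c₀ included, 26 filters, Hamming, 0.97) are the dominant
speech-tooling defaults; the alternatives are not distinguishable from the
published geometry.

The 26 × 298 matrix is min–max normalized per image to [0, 255] (a constant
matrix maps to mid-gray 128) and linearly interpolated along time to width
599. The stated hop cannot itself produce 599 frames from a 3 s clip; the
pipeline treats 599 as the canonical image geometry and meets it by
interpolation, preserving both the framing arithmetic and the layout. The
twelve per-question images are stacked top-to-bottom in the fixed question
order; `composite_image` orders tiles itself and rejects missing,
duplicated, or mis-sized tiles.

## Augmentation

Two texture-preserving operators only: per-pixel brightness scaling
(clamped 8-bit) and rightward column shift with mid-gray fill — a shifted
image reads as a delayed response preceded by silence. Geometric transforms
(flips, crops, rotations) are deliberately excluded as they would corrupt
the spectro-temporal texture. Defaults: brightness factors on the
0.85–1.15 grid (step 0.05), shifts on 0–0.20 (step 0.05), tenfold
expansion, copy 1 the untouched original, the remaining nine drawn from the
grids by a seeded generator (the draw is sampled, not exhaustive; the
original selection procedure is not specified beyond the grids).
`grid_validate` reruns a user-supplied train/eval callback for each
candidate brightness or shift setting alone and flags the best setting by
accuracy with an F1 tie-break.

By default augmentation happens **after** splitting and only on the
training portion — augmented copies of one participant never appear in two
partitions. `paper_mode` reproduces the original augment-everything,
image-level-split protocol for comparison; its headline numbers are
optimistic by construction, which is precisely why it is a flag.

## Classifier and training

`small_cnn` is the reference desk-scale model: composites are mapped to
[−0.5, 0.5] (centering keeps the first layer well conditioned, since
composites are bright on average), bilinearly resized to 40 × 76, then
passed through three 3 × 3 conv blocks (8/16/32 channels, ReLU, 2 × 2
average pooling after the first two), global average pooling, and a single
logistic unit; binary cross-entropy, AdaMax. The gradient implementation is
verified against numerical differentiation in the test suite. The five
large ImageNet architectures are pluggable through a registry rather than
bundled: the pipeline's claims are testable with any image classifier, and
the contract a backbone must satisfy (`preprocess` / `loss_and_grads` /
`predict_proba`) is the module surface.

Training: batch size 4, at most 60 epochs, early stop after 3 epochs
without validation-loss improvement, best-validation weights restored. The
published learning rate 1e-6 — appropriate for fine-tuning large pretrained
backbones — remains the `TrainConfig` default; pipeline runs with the
from-scratch numpy CNN pass 1e-2 explicitly (its convergence rate at batch
size 4 on ~600 images). A patience no smaller than `max_epochs` simply
disables early stopping, keeping one-epoch schedules expressible.

## Evaluation

AD is positive throughout. Sensitivity, specificity, accuracy, PPV, NPV and
F1 follow the confusion identities; any zero-denominator metric is reported
as NaN, never coerced. ROC sweeps thresholds over unique scores; AUC is the
trapezoid under that curve and equals the tie-corrected Mann–Whitney
statistic (property-tested on 1,000 random score sets). Five-fold CV is
stratified with a 0.1 validation carve-out per fold; fold panels are
aggregated as the unweighted mean (pooling across folds is the other
defensible choice; the mean was chosen so each fold's test set weighs
equally regardless of rounding).

## Problem sizes and determinism

The standard study condition is 40 participants per class (80 composites,
800 after tenfold augmentation, 640 in an image-level training split). The
end-to-end checks run exactly this size: a strong-effect cohort must reach
≥0.9 held-out accuracy under the subject-wise protocol, and a null-effect
cohort must stay inside the 95% binomial band around 0.5 — together these
bracket signal recovery and leakage. Smaller cohorts (4–16 per class)
appear in unit tests and examples where only plumbing is exercised. One
global seed derives all stage seeds via CRC32 of `"{seed}:{stage}"`;
everything downstream (profile jitter, waveform noise, augmentation draws,
split assignment, weight init, batch order) flows from these, so a rerun of
one config reproduces every CSV bit-identically on CPU.

## Known limitations

- Synthetic speech is a caricature: class separation rests on silence
  layout and tempo-like cues, so reported accuracies say nothing about
  clinical performance on real recordings.
- The 599-width interpolation convention is ours; any analysis comparing
  raw frame indices across implementations must account for it.
- Whether the original five-fold metrics were fold-averaged or pooled, and
  whether its backbones were pretrained, is unspecified; this package
  documents its own choices (mean aggregation; backbone-agnostic registry)
  rather than claiming fidelity on those points.
- `small_cnn` sees an 8×-downsampled composite; fine cepstral detail is
  available to plugged-in backbones but unused by the reference model.
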