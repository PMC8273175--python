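# Methods

This note documents the models, procedures, parameter choices and known
limitations of `spectroseize`. Sizes quoted for tests refer to the defaults
in the shipped suites; everything is configurable through the public API.

## Data model

An ECoG record holds 1–4 channels at 250 Hz, 30–180 s long, with an
optional 0-based storage-trigger index and a record type (`LE` — long
episode, i.e. stored on detection of sustained abnormal activity —
`scheduled`, `magnet`, `saturation`). Time is always `index / 250` s. On
disk a record is a CSV (`sample_index, ch1..ch4` in µV) plus a JSON sidecar
with the metadata; this container was chosen over EDF to keep the package
dependency-free and its tests hermetic. Channel labels live in a CSV table
keyed by `(patient_id, record_id, channel_index)` with a `source` column
(`centroid`, `propagated`, `corrected`, `expert`) that records how each
label arose.

## Synthetic ECoG generator

The simulator emulates the statistical structure the pipeline depends on,
not biophysics. Per patient (a `PatientArchetype`):

* **Background**: a sinusoid at the patient's dominant rhythm
  (`base_freq_hz`, default 8 Hz) plus low-passed (40 Hz) white noise,
  scaled by `noise_level` (default 20 µV RMS). Amplitude scales are free
  parameters chosen to look plausible; nothing downstream depends on them
  because image rendering is amplitude-free (below).
* **Seizures**: each patient has a small library of stereotyped morphology
  templates drawn once from the archetype seed — a logarithmic chirp from
  `f0` (≈ base rhythm) to 2–4× base, 14–30 s long, with a sigmoidal
  amplitude rise to 3.5–6× the background scale and a channel mask. A
  record contains a seizure with probability `seizure_rate`; the inserted
  discharge always lasts ≥ 10 s (2,500 samples), mirroring the labeling
  rule that separates electrographic seizures from shorter rhythmic
  activity. Morphologies produce the rising narrowband spectral band the
  saliency analysis expects.
* **Trigger alignment**: long-episode records place the detection trigger
  at ≈ 2/3 of the record (± 3 s), 1–4 s after seizure onset — the device
  stores a fixed pre/post-trigger window, so discharges are roughly
  aligned in time across records. This alignment is what makes records of
  the same morphology mutual near-neighbours in image space; it is a
  property of the acquisition, not a convenience.
* **Interictal activity**: biphasic ~70 ms spikes (Poisson, `spike_rate`
  per minute) and, with per-channel probability `burst_rate` (default
  0.35), short (< 10 s) *non-evolving* rhythmic bursts following a
  patient-stereotyped template whose peak power lies in the seizure range.
  The bursts matter: without high-contrast non-seizure content, per-image
  normalisation would let a classifier separate the classes from the
  normalised background level alone, and its saliency would be diffuse.
  With them, the discriminative feature is the sustained, evolving
  structure of the discharge — the feature the method is about.
* **Noise / LVF channels**: with small per-record probabilities (0.08,
  0.05), one channel carries broadband high-amplitude noise bursts
  (labeled `noise`) or a few seconds of 40–60 Hz low-amplitude activity
  (labeled `low_voltage_fast_only`).
* **Stimulation artifacts**: a run of samples set exactly to the blank
  value (0 µV by default) followed by a decaying recovery transient.

All randomness flows through one `numpy.random.Generator`; a fixed
archetype seed and generator state reproduce records byte-identically.
Labels are assigned per channel: `ictal` where a seizure was inserted,
`noise`/`low_voltage_fast_only` for the special channels, `interictal`
where spikes or bursts landed, otherwise `baseline`.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: realistic seizure electrodynamics (propagation
across channels with delays, post-ictal suppression), non-stationary
background states (sleep/wake), electrode drift, or the long tail of
ambiguous activity that makes real labeling hard (`unsure` labels never
arise synthetically). Results on synthetic data bound the pipeline's
correctness, not its clinical accuracy.

## Preprocessing

* **Blank detection**: maximal runs of ≥ 5 consecutive samples exactly
  equal to the blank value (20 ms — too long for natural zero crossings;
  device blanking writes a constant).
* **Artifact rejection**: each run is extended by 10 samples before and 30
  after (covering the recovery transient), extended regions are merged
  *before* removal so margins are never double-counted, clipped at record
  edges, and the flanking data concatenated. All channels of a record are
  cut with the union mask so they stay sample-aligned, and the trigger
  index is shifted by the samples removed before it. The implementation is
  tested for exact agreement with an independent mask-and-compress oracle
  on 1,000 random blank patterns.
* **Length normalisation** to 90 s (22,500 samples): records < 80 s get
  the disparity prepended as a duplicate of their start (tiled if the
  record is shorter than the disparity) or as zeros (`zero_pad` mode);
  records > 100 s keep 60 s before to 30 s after the trigger, with the
  window shifted inward when the trigger sits near an edge; records of
  80–100 s pass through unchanged (the image resize absorbs the residual
  spread). Multi-trigger records use the last trigger.
* **60 Hz notch** (for mains-contaminated scalp EEG, not device ECoG):
  zero-phase second-order IIR notch, quality factor 30 — ≥ 20 dB at 60 Hz,
  passband (≤ 40 Hz) within 1 % of unity.

## Spectrograms and image dialects

One-sided Hann-window PSD, 256-sample window, 128-sample step, 0–125 Hz
(129 bins; `⌊(n − 256)/128⌋ + 1` frames), in dB with a 1e−12 power floor.
Rendering min-max normalises each image to [0, 1] (a constant matrix maps
to mid-scale), draws low frequencies at the bottom, applies jet or
grayscale (three identical channels), nearest-neighbour resizes, and
rescales to [−1, 1]. Per-image normalisation makes the pipeline invariant
to global amplitude scaling of the raw trace — tested as exact pixel
equality under gain changes. Two dialects: `embedding` (299×299, the input
contract of the pretrained feature extractor) and `classifier` (224×224
default; the side is configurable and the shipped tests use 32×32, see
below). PNGs store pixel `p` as `round((p+1)/2·255)`, so a save/load round
trip is exact to one 8-bit step.

## Embedding and clustering

The deep-feature extractor contract is image → 8×8×2048 feature map,
flattened row-major to 131,072 values per channel; four channel blocks
concatenate to a 524,288-feature record vector with zero-filled blocks for
absent channels. For hermetic operation the package ships a **surrogate
extractor** (clearly synthetic: a seeded random projection): the grayscale
image is cut into an 8×8 grid of 37×37 patches and each patch is projected
by one fixed Gaussian matrix to the feature depth. It is deterministic,
locality-preserving, and uses every interior pixel; by the
Johnson–Lindenstrauss property it approximately preserves image-space
Euclidean geometry, which is what the downstream clustering consumes. A
real pretrained backbone can be plugged in behind the same callable
interface. The surrogate's feature depth is configurable (tests use 32,
i.e. 2,048-feature channel vectors) purely for memory/speed; depth 2048
reproduces the standard sizes.

PCA is fitted on `min(N, 1024)` randomly selected record vectors with
`min(50, sample, rank)` components and applied to all records; t-SNE
(perplexity 30, clipped below the sample count; PCA initialisation; seeded)
produces the 2-D embedding. Whitening is not applied. Clustering uses a
Bayesian Gaussian mixture in the 2-D space: `n_components =
min(max(⌊N/100⌋, 10), N)` (the rule value is reported; the cap is an
implementation requirement of the mixture fit), full covariances,
Dirichlet-process weight prior, ≤ 500 iterations, seeded. The effective
cluster count — components that actually received members — can be
smaller. Degenerate input (all points identical) yields one cluster rather
than an error. The centroid record of a cluster is the member minimising
Euclidean distance to the cluster's *member mean* (not the mixture
component mean — the member mean guarantees the centroid is a real,
labelable record), with ties broken by smallest record id.

## Labeling workflow

Centroid labels propagate verbatim to every member channel
(`source=propagated`; the centroid's own rows are `source=centroid`).
Review queues order members by ascending Euclidean distance to the
*centroid record's* embedding point (ties by record id), 15 per page, so
`⌈n/15⌉` pages with corrections concentrating on late pages. Corrections
replace the label, set `source=corrected`, and keep the prior value in a
`previous_label` audit column — the workflow needs reproducible relabeling
even though the storage format is not prescribed anywhere. Binary mapping:
`ictal` → seizure; `interictal`, `baseline`, `noise`,
`low_voltage_fast_only` → non-seizure; `unsure` → excluded from all
training and evaluation. Record-level classes use OR over channels.
Labeler agreement is percent identical binary classes over the common keys
(after dropping excluded rows; mismatched key sets are an error), reported
to one decimal.

## Classifier harness

Architectures: `cnn6` (conv 32-64-128-128, each 3×3 + 2×2 max-pool, then
dense 50 and a 2-unit softmax head — 1,495,384 trainable parameters at
224×224×3), `cnn7` (adds a conv-256 block; dense 64), `cnn12` (VGG-style
2×32, 2×64, 2×128, 2×256, 2×256 with pooling per pair; dense 128), and
ResNet18/50. The plain CNNs build as trainable networks on the numpy
engine; the residual nets are represented structurally for exact
trainable-parameter accounting (Keras-convention conv biases and
batch-norm scale/shift counted, running statistics excluded): 23,538,690
(23.5 M) for ResNet50 and 11,182,338 (11.2 M) for ResNet18 with the 2-unit
head. Training the residual stacks is out of scope for this package — the
protocol experiments that need training use the plain CNNs. The layer
counts of the shallow stacks follow the published depths; their exact
filter complements are this package's own declared choice.

Training: minibatch Nadam (or Adam) at batch 32, learning-rate decay 0, at
most 70 epochs; stop when no epoch improved the best validation accuracy
by ≥ 0.1 percentage points within the last 10 consecutive epochs
(best-so-far is the stricter of the two readings of "improvement" and is
the one implemented); the weights of the best-validation epoch are
restored. Default learning rates are 1e−6 for the plain CNNs and 1e−7 for
residual nets — the values appropriate to the full-scale study — but the
synthetic desk-scale experiments pass 1e−3 explicitly: a small
from-scratch CNN on 32×32 synthetic images sits in a different optimisation
regime and would not move at 1e−6 within 70 epochs. Non-finite loss raises
an error carrying the epoch index. All stochasticity (shuffles,
initialisation, downsampling) derives from the config seed.

Splits are always by patient and guarded against leakage at construction.
The fold design randomly partitions 113 patients 72/18/23 (rounded
fractions 0.64/0.16/0.20 for other cohort sizes), independently per fold.
The data-scaling design sorts 105 patients into 5 bins of 21 by labeled
record count, draws `s/5` patients per bin for each training size
`s ∈ {10,…,80}`, extends smaller sets to larger ones (nestedness), and
draws `max(5, ⌈0.2 s⌉)` validation patients per size from the remaining
pool, spread as evenly as possible across bins. Class balancing randomly
downsamples the majority class to the minority count, on the training
split only.

Desk-scale choices in the shipped tests: classifier images at 32×32 (the
four pooling stages then end at a 2×2 map; 24×24 ends at 1×1 and measurably
hurts held-out accuracy), 2,000 training channel images from five synthetic
patients, one validation and two test patients, three training seeds.
These sizes keep the full suite a few minutes on one CPU while exercising
the complete protocol.

## Evaluation

Class accuracy is per-class recall; "overall" is the unweighted mean of
the two, making it a class-balanced quantity on imbalanced test sets; F1
(seizure positive), precision–recall curves over all distinct predicted
probabilities, and integer confusion matrices accompany it. Empty truth
classes flag their accuracy as undefined rather than crash. Record-level
evaluation ORs the channel predictions and takes the max channel
probability as the record probability. Analytic baselines:
`1 − (1 − p)^n` for the probability a random per-channel classifier flags
an n-channel record (0.9375 at p = 0.5, n = 4), checked against
Monte-Carlo aggregation; and `(1 − acc/100) · 3600/segment` FP/h/channel
for continuous-data extrapolation. Saliency is `|∂ logit_c / ∂ pixel|`,
reduced over colour channels by max and min-max normalised; for a linear
model it provably equals the normalised class-weight magnitudes, which the
tests assert, and the engine's input gradients are verified against finite
differences.

## Numerical notes and limitations

* The numpy engine stores activations in float32; gradient checks
  therefore use a 1e−3 finite-difference step.
* Max-pooling crops odd trailing rows/columns rather than padding.
* t-SNE and the mixture fit are seeded but remain sensitive to their
  seeds in the usual ways; the clustering tests fix seeds and use
  archetypes with well-separated morphologies and no burst trains — under
  burst-heavy archetypes the surrogate extractor's Euclidean geometry is
  not discriminative enough for high cluster purity, which a semantic
  (pretrained) backbone would be expected to restore.
* The review-queue, correction and agreement operations cover the
  *logic* of the labeling GUI; no interactive tool is included.
* Scalp-EEG generalisation support stops at the 60 Hz notch; montage
  handling for external corpora is out of scope.
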