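# Methods

`ehgpipe` implements a complete, testable version of a CNN-based procedure
for recognizing uterine contractions (UCs) in multichannel
electrohysterogram (EHG) recordings, anchored on the simultaneously recorded
tocodynamometer (TOCO) trace. This note records the models, the parameters
that matter, and the design choices made where the procedure left them open.

## The classification problem

A 16-electrode abdominal grid records the uterus's electrical activity at
200 Hz alongside a TOCO pressure trace. Each annotated TOCO peak defines a
contraction event. The task is binary: does a fixed-duration EHG window
contain a contraction (UC) or not (non-UC)? The standard training unit is a
60 s window symmetric around the TOCO peak; matched non-UC windows are taken
at the midpoint between two adjacent peaks. The scientific question the
positional analysis answers is *which part* of the peri-contraction signal
carries the recognizable signature: the two-minute span around each peak is
tiled into 10 s, 20 s, and 30 s windows (`10_L6..10_L1`, `10_R1..10_R6`,
`20_L3..20_L1`, `20_R1..20_R3`, `30_L2..30_L1`, `30_R1..30_R2`; index counts
outward from the peak, `d_L1` ends at the peak and `d_R1` starts at it), and
a model trained only on 60 s windows rates every positional window.

## Preprocessing

Signals are decimated 200 Hz → 20 Hz (8th-order Butterworth anti-alias
lowpass at 0.8× the target Nyquist, then integer decimation) and bandpassed
with a 5th-order Butterworth at 0.1–4 Hz, the band carrying uterine
electrical bursts. "5th order bandpass" is read conventionally: an order-5
analog prototype bilinear-transformed into a 10-pole digital bandpass.
Filtering is zero-phase (forward–backward) by default because the
peak-anchored segmentation depends on the temporal alignment between EHG
bursts and TOCO peaks; a causal single-pass mode is exposed
(`FilterSpec(zero_phase=False)`). The TOCO trace is decimated but not
bandpassed — its near-DC bump would not survive the 0.1 Hz high-pass edge.

## Segmentation conventions

Times are seconds from record start; sample index = `round(t * fs)`;
intervals are half-open `[start, end)`. Windows that would cross a record
boundary are skipped with a logged reason, never truncated. A between-peaks
gap qualifies for a non-UC window when `gap >= duration + guard`; the guard
defaults to 120 s so that a 60 s midpoint window stays at least 60 s away
from both neighboring peaks, keeping it clear of the whole ±60 s positional
span (a smaller guard would let "non-contraction" windows overlap
contraction bursts and poison the labels). Positional non-UC windows are
anchored at the non-UC midpoint with the same offsets as the UC windows, so
every position label has matched examples of both classes.

## Signal-to-image encoding

Each single-channel segment is rendered as a dark trace on a light
background (no axes), time mapped linearly to width, and the raster fixed at
482×482 px by default (128×128 for the CPU-scale model). Rendering is a pure
deterministic function of the samples: the trace is drawn on a
double-resolution native raster and area-averaged down, which anti-aliases
the line; when a segment has more samples than columns, each column is
painted with the min–max envelope of all samples mapping into it — what a
strip chart would show — using integer-exact binning, so time-reversing a
segment mirrors the raster bit-exactly.

Amplitude handling was genuinely open. Per-segment min–max scaling (the
common plotting default) is the `render_segment` default. The pipeline,
however, renders against a **fixed per-channel amplitude range** taken from
the whole preprocessed recording. The reason is structural: stretching
windows of different durations to a fixed width destroys every
time-scale-dependent texture cue, so a model trained on 60 s images can only
transfer to 10–30 s windows through cues that survive the stretch. Amplitude
contrast — bursts are an order of magnitude larger than background — is
exactly such a cue, and per-segment normalization erases it. With fixed
scaling a contraction window renders as a large oscillation spanning the
image and a background window as a small central ribbon, at any duration.

## The CNN

An 11-layer AlexNet-style stack (see `ehgpipe.cnn.arch` for the exact
table): Conv(27, stride 5)@96 → MaxPool(2,3) → Conv(2,1)@256+LRN →
MaxPool(2,2) → Conv(3,1)@384+LRN → Conv(3,1,pad)@384 → Conv(3,1,pad)@256 →
MaxPool(3,2) → FC 4096 → FC 4096 → FC 2 + softmax, with ReLU after every
conv/FC and dropout 0.5 on the wide FC layers. With pad=1 on the two padded
conv layers the spatial trace on a 482-px input is
482→92→31→30→15→13→13→13→6, which is the self-consistent reading of the
published layer table (its literal pad=2 would give 15→17 and break the
narrated sizes; `build_architecture("paper", pad_literal=True)` keeps the
literal variant available). Local response normalization uses
`local_size=5, alpha=1e-4, beta=0.75` and `k=1` (the framework default the
original implementation implies), normalizing across channels with windows
truncated at the borders.

The `scaled` variant — input 128×128, filter counts divided by 8, 256-wide
FC layers, same layer sequence — exists so the full procedure runs in
minutes on one CPU. Its geometry needs pad=1 on the fifth conv layer as
well, otherwise the 3×3 map collapses below the final 3×3 pool.

All layers, including backpropagation through convolution (im2col/col2im),
overlapping max-pooling, LRN, and inverted dropout, are implemented in
NumPy; no deep-learning framework is used.

### Training

Mini-batch SGD with momentum 0.9, weight decay 5e-4, learning rate 1e-3
multiplied by 0.1 every 10 epochs, up to 20 000 iterations (the published
"batch gradient descent" is read as mini-batch SGD — a full batch over
~10^5 images is implausible — and "gamma" as an alias of the drop factor).
Biases start at 0.1 ("small positive values in (0,1)"). Weight
initialization: the reference variant keeps the published Gaussian std 0.1;
the scaled variant defaults to fan-in-scaled (He) initialization because
std 0.1 with fan-ins of several hundred saturates the softmax at
initialization on [0,1]-intensity images. Batch size is not published;
defaults are 64 (reference) and 16 (scaled). Pixel intensities are fed as
[0,1] with no mean subtraction. Every random choice (init, shuffling,
dropout, splits) flows through one seeded NumPy generator, so training is
bit-reproducible.

### Event-level decisions

One contraction event yields 16 single-channel images. Evaluation counts
*events*, not images (the published fold counts of ~1427 per class match
event counts, not 16× image counts), so the 16 per-channel probability
vectors are aggregated: `mean` (average probabilities, then argmax — the
default) or `majority` (modal vote, ties broken toward non-UC). Per-image
metrics are also logged.

## Evaluation

With UC positive: SE = TP/(TP+FN), SP = TN/(FP+TN), ACC = (TP+TN)/total.
Computation keeps full precision; reporting rounds to two decimals with
round-half-away-from-zero, matching clinical-table presentation. Fivefold
cross-validation stratifies events by class (fold sizes per class differ by
at most one; 7136 per class splits as 1428 + 4×1427); within each training
set a seeded stratified 80/20 train/validation split tunes nothing but
monitors convergence. The averaged row is reported both as metrics of the
count sums across folds (the headline, matching the published convention)
and as the mean of per-fold metrics. CV splits at event level, mirroring the
published procedure; an optional subject-grouped mode is a recognized
improvement (event-level splitting lets windows from one subject appear in
both train and test) but is off by default to match the procedure being
reproduced.

## Positional statistics

Sensitivity (or SP/ACC) is compared across same-duration window positions
with one-way ANOVA followed by Tukey's HSD at α = 0.05. The original report
does not state its replication unit; here replicates are independent
training runs with different seeds (default n = 3–5 in the pipeline), and a
per-fold mode is available by passing per-fold values. Degenerate input
(all groups constant and equal) takes the p = 1 path. ANOVA/Tukey are
delegated to scipy/statsmodels and verified against the closed-form F
statistic in the tests.

## Synthetic data

The generator emulates the structure of a 16-electrode pregnancy monitoring
database well enough for every pipeline stage to be exercised with known
ground truth:

* **Contraction bursts**: band-limited Gaussian noise (default 0.3–1 Hz,
  inside the analysis band) under a Gaussian envelope (default width 40 s,
  varied ±20% per event), present on all 16 channels with per-channel
  amplitudes drawn log-uniformly from [0.5, 2] (electrodes sit at different
  distances from the active region). A broadband carrier rather than a pure
  tone prevents the classifier from keying on a single frequency.
* **Background**: stationary colored noise — dominant 1/f-type baseline
  wander (2nd-order lowpass at 0.3 Hz) plus a 0.35-relative broadband
  component at 1.5–4 Hz. Real inter-contraction EHG statistics are not
  characterized in the source material; this spectrum is an assumption
  chosen to be physiologically plausible for bandpassed abdominal signals.
* **TOCO**: raised-cosine bumps (60 s base width, unit amplitude) centered
  at the annotated peaks, which are jittered uniformly within ±5 s of the
  true burst centers to mimic imperfect EHG–tocograph synchronization.
* **SNR**: burst RMS is `10^(snr_db/20)` × background RMS (default 20 dB).
* Defaults: 3 recordings × 8 contractions, 2400 s records, ≥240 s between
  peaks so clean non-UC windows exist. Identical (config, seed) reproduces
  records bit-exactly.

What the generator does **not** model: propagation of the burst across the
electrode grid, maternal movement and electrode artifacts, labor-vs-
pregnancy differences, gestational-age effects, or realistic non-UC events
(fetal motion, Braxton–Hicks-like activity). Passing the recovery tests
therefore shows the pipeline is correct and the method behaves as described
on signals with the assumed structure — it does not certify the published
accuracy figures on real recordings, which would require the real database
and training at two orders of magnitude larger scale.

## Problem sizes used in the tests

The recovery study trains the scaled CNN on two synthetic recordings
(16 events × 16 channels per class-ish, ≥200 images per class at 128 px),
10 epochs, three seeds; the acceptance bar is validation accuracy ≥0.9 in a
majority of seeds and, in a majority of seeds, strictly higher sensitivity
at the peak-adjacent windows (`d_L1`/`d_R1`) than at the outermost windows
of every duration — the qualitative positional finding the method exists to
demonstrate. The cross-validation and pipeline tests run the same code at
smaller sizes (fewer channels or events, 2 epochs) to exercise structure
rather than learning capacity.

## Known limitations

* The published headline metrics on the real database are out of reach at
  this scale and are not claimed; the package reproduces the published
  *metric arithmetic* exactly from the printed confusion counts and the
  qualitative positional ordering on synthetic data.
* Two cells of the published tables are internally inconsistent with their
  own printed counts (one fold's ACC, and one positional row whose counts
  appear to carry a ±100 digit error); the corresponding checks assert the
  printed values and fail, deliberately, rather than hiding the
  discrepancy.
* WFDB support is a minimal format-16 subset (text header + int16 signal
  file; annotations in a plain-text sidecar, not binary annotation files).
  It has not been validated against the real database's files.
* Event-level CV splitting (no subject grouping) reproduces the published
  procedure but optimistically biases real-data estimates.
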