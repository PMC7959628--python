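# Methods

`lungsound` classifies auscultated lung-sound recordings as COPD vs non-COPD
from a single fixed-size time-frequency image per recording. This note
documents the model and procedure, the parameters that matter, the synthetic
data the package is validated on, and the numerical choices made where the
design was open.

## Problem and pipeline

Input is a set of mono WAV recordings of very uneven length (auscultation
corpora typically run 10-90 s per file) with a per-recording diagnosis
string. The diagnosis is binarized: exactly "COPD" (case-insensitive) is the
positive class; every other diagnosis (healthy, asthma, URTI, LRTI, ...) is
negative. The pipeline is:

1. **Canonicalization** (`audio_io`): decode to float in [-1, 1], average
   stereo to mono, resample to 22 050 Hz, and trim/zero-pad every recording
   to exactly 20 s. Trimming keeps the head of the recording and padding
   appends zeros at the tail — the simplest deterministic rule; nothing in
   the task suggests the diagnostic signal concentrates elsewhere.
2. **Feature extraction** (`features`): one of five 40-bin representations,
   each a 40 x 862 matrix (862 = floor(20 * 22050 / 512) + 1 centered frames
   at hop 512).
3. **Augmentation** (`augmentation`): the minority class is grown to parity
   with label-preserving waveform transforms, training folds only.
4. **Classification** (`model`): a small CNN maps the 40 x 862 x 1 image to
   two softmax probabilities.
5. **Evaluation** (`evaluation`): sensitivity, specificity, their mean (the
   ICBHI challenge score), accuracy and trapezoidal ROC AUC, under a
   stratified 10-fold cross-validation or a stratified single split.

The 22 050 Hz / hop 512 / centered-framing combination is the canonical
analysis grid of the whole package: it is the only common default set for
which a 20 s clip yields exactly 862 frames, the time extent the CNN's shape
trace assumes.

## Features

All five extractors share one STFT front end: periodic Hann window,
`n_fft = 2048`, hop 512, frames centered by zero-padding `n_fft/2` samples on
each side. Power is `|STFT|^2`.

- **Mel spectrogram** — 40 triangular mel filters (HTK scale, 0 Hz to
  Nyquist) applied to the power spectrogram. Entries are non-negative and
  scale with the square of waveform gain.
- **MFCC** — orthonormal DCT-II of `log(mel + 1e-10)`, 40 coefficients.
  With 40 mel bands the DCT is square, so MFCC is a lossless rotation of the
  log-mel image; the additive guard keeps silence well-defined.
- **Chroma (STFT)** — FFT-bin power folded onto an octave-periodic profile
  (reference C1 = 32.703 Hz), then per-frame max normalization into [0, 1],
  which makes the feature invariant to waveform gain.
- **Chroma (constant-Q)** — a pseudo-CQT (triangular weights, one bin
  spacing wide in log2 frequency, geometric centers from C1 at `n` bins per
  octave) folded and max-normalized the same way. A filterbank approximation
  of the CQT from a single STFT is used rather than a multirate CQT; at the
  40-bins-per-octave resolution used here the approximation error is far
  below the class signal.
- **CENS** — per-frame L1-normalized chroma, quantized through thresholds
  (0.05, 0.1, 0.2, 0.4) in steps of 0.25, smoothed over a 41-frame Hann
  window (no downsampling), then per-frame L2-normalized. Robust to dynamics
  and local articulation.

**40 chroma bins.** The bin count is fixed at `n = 40` for every feature for
consistency, including the chroma variants, which therefore use 40 bins per
octave-folded profile instead of the conventional 12 pitch classes. This is a
deliberate, slightly unusual reading kept for cross-feature consistency; the
conventional 12-bin chroma remains available (`n_bins=12`) and is what the
pitch-class oracle tests use (a 440 Hz tone must fold to class A = bin 9).

## Augmentation

Four waveform operators, applied cyclically to minority-class clips until the
class counts are equal; originals are always kept and every synthetic clip
records its parent id and technique:

- **Loudness** — multiplicative gain uniform on [0.6, 1.4], then hard clip
  to [-1, 1]. The range is read as a gain factor of 0.6-1.4x: a
  fraction-of-a-percent loudness change would be inaudible and could not
  alter any classifier.
- **Mask** — 2 disjoint random intervals of 5% of the clip each are zeroed.
  Placement uses the sorted-uniform gap construction, so disjointness is by
  construction, and the zeroed fraction is exact.
- **Shift** — circular rotation by a uniform offset in [-len/2, +len/2].
  Circular (rather than zero-fill) shifting loses no signal and preserves
  the sample multiset exactly, which makes it cleanly testable.
- **Speed** — resampling-based rate change uniform on [0.5, 2.0]: duration
  scales by 1/rate and pitch by rate, after which the clip is re-fixed to
  20 s so downstream shapes are stable.

Augmentation runs on raw audio before feature extraction (speed and loudness
are waveform operations by nature), and only ever inside a training split —
held-out data is never augmented, so reported metrics cannot leak synthetic
copies of test recordings into training.

## Classifier

A sequential CNN on the 40 x 862 x 1 image:

| block | layers | output |
|---|---|---|
| 1 | Conv2D(16, 2x2, ReLU, valid) - MaxPool(2x2) - Dropout(0.2) | 19 x 430 x 16 |
| 2 | Conv2D(32, ...) - MaxPool - Dropout | 9 x 214 x 32 |
| 3 | Conv2D(64, ...) - MaxPool - Dropout | 4 x 106 x 64 |
| 4 | Conv2D(128, ...) - MaxPool - Dropout | 1 x 52 x 128 |
| head | GlobalAveragePooling2D, Dense(2), softmax | 2 |

Convolutions are unpadded and pooling uses floor division — both forced by
the shape trace (a "same"-padded first block would give 20 x 431, not
19 x 430). Total trainable parameters: 43 570. The network is implemented
directly on numpy: im2col convolutions backed by BLAS matmuls, strided-view
max pooling with first-element tie-breaking, inverted dropout (training
only), explicit backpropagation, and Adam (step 1e-3, decays 0.9/0.999) on
categorical cross-entropy. All arithmetic is float32; weight initialization
(He normal), batch shuffling and dropout masks are all driven by explicit
seeds, so building and training are bit-reproducible.

Training defaults are 50 epochs at batch size 32 — declared package
defaults, overridable in `TrainConfig`. Before entering the CNN, feature
matrices are standardized per bin row with statistics fitted on the training
portion only; raw MFCCs put coefficient 0 two orders of magnitude above the
rest, and row-wise standardization is what lets one optimizer setting train
all five feature kinds.

## Evaluation protocol

The positive class is COPD. Sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP); an empty denominator raises rather than silently reporting 0.
The ICBHI score is the arithmetic mean of Se and Sp. ROC points come from
score thresholds (both classes must be present) and AUC is the trapezoidal
area, which equals the Mann-Whitney pair-ordering statistic; the test suite
verifies that equality against a brute-force pair count.

Cross-validation is stratified k-fold (default k = 10) with shuffling under
a fixed seed. Per-fold metrics are reported alongside pooled metrics
computed on the summed test-fold confusion counts (micro-average). Report
tables round half-up to 2 decimals; rounding is performed on the shortest
decimal representation of the value so that, e.g., a mean of 0.595 prints as
0.60 despite binary floating point storing it a hair below the tie.

## Synthetic data

The simulator generates the statistical shape the pipeline assumes, not
physiology:

- **Normal class**: white noise band-passed to 100-2000 Hz (the energetic
  band of chest-wall breath sounds), amplitude-modulated by a squared-sine
  envelope with cycle length uniform in [2.5, 5] s, plus broadband sensor
  noise at 0.1 relative RMS.
- **COPD class**: the same breath bed plus (a) a wheeze — fundamental
  uniform in [100, 1000] Hz with one half-amplitude harmonic, gated to the
  expiratory half of each cycle at 6 dB SNR over the gated breath RMS — and
  (b) crackles — 5-15 ms exponentially damped tone bursts, Poisson-placed
  at 2 events per cycle.

Clip durations are uniform in [10, 90] s so duration-fixing is exercised in
both directions, and the class mix defaults to 4:1 COPD-heavy so class
balancing is exercised realistically. Everything is reproducible from one
seed via per-clip child seeds.

Defaults were chosen once as a realistic caricature: wheezes in the
100-1000 Hz band at single-digit-dB SNR and a few crackles per cycle match
how adventitious sounds are usually characterized, and they make the task
learnable but not trivial. What passing tests show is that the pipeline
recovers a genuine class-conditional spectral difference and reports chance
when none exists; they do not show field performance on real auscultation,
which varies with equipment, chest location and patient in ways this
generator does not model.

The end-to-end validation runs the MFCC pipeline on 100 generated clips
(80 COPD / 20 non-COPD, dataset seed 7) with a stratified 75/25 split,
training-fold-only augmentation and 30 training epochs — a problem size
chosen so the whole check runs in minutes on one CPU while leaving a wide
margin over its thresholds (held-out ICBHI >= 0.90, AUC >= 0.95, and
chance-level AUC within [0.35, 0.65] when wheeze and crackles are disabled).

## Numerical choices and edge cases

- `log(x + 1e-10)` wherever a log of power is taken; silent input yields
  all-zero mel/chroma features, not NaNs.
- Per-frame normalizations guard zero frames (a zero column stays zero).
- Max-pool ties resolve to the first element of the window in row-major
  order; gradient flows only to the winner.
- PCM-16 I/O uses symmetric scaling by 32767 on read and write, so a write
  -> read round trip errs by at most half an LSB; the single extreme code
  -2^15 clips to -1.
- Speed factors are approximated by rationals (denominator <= 1000) for
  polyphase resampling.
- Stage seeds fan out from the run seed by fixed offsets, so any stage can
  be rerun in isolation with identical randomness.

## Known limitations

- The synthetic corpus is a spectral caricature; no claim is made about
  real-world diagnostic performance.
- The 40-bin chroma reading trades pitch-class convention for cross-feature
  consistency; both resolutions are exposed.
- The CNN is CPU-oriented numpy; it is intentionally small (43 570
  parameters) and not a general deep-learning framework.
- Cycle-level adventitious-event detection (locating individual wheezes or
  crackles) is out of scope; the classifier operates on whole recordings.
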