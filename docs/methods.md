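# Methods

This note documents the models, conventions and numerical choices behind
`emgpix`, and what its synthetic experiments do and do not demonstrate.

## Problem setting

Surface electromyography (sEMG) armbands record the electrical activity of
forearm muscles on 8 or 16 differential electrode channels. Because distinct
hand gestures recruit distinct parts of the forearm muscle ring, the spatial
pattern of activity across channels — together with its spectral content —
identifies the gesture. Myoelectric control needs a decision within roughly
300 ms, so classification operates on 250 ms records. `emgpix` implements
the full decision pipeline (noise reduction → segmentation → image encoding
→ CNN classification → condition comparison) and, because the original
30-subject dataset is not public, a synthetic generator that reproduces the
acquisition protocol's structure.

## Synthetic sEMG model

Each recording is one gesture hold of `hold_duration` seconds sampled at
`fs` per channel:

    s_c(t) = a_c · e(t) · g_c(t)  +  A · sin(2π·50·t + φ)  +  d  +  σ · w(t)

* **Carrier** `g_c(t)`: independent per-channel Gaussian white noise,
  band-passed (4th-order Butterworth, zero-phase) to `emg_band` = 20–450 Hz
  — the band where surface-EMG energy concentrates — and normalized to unit
  RMS. Surface EMG is well approximated at this level by band-limited noise
  whose *amplitude* carries the information; no motor-unit structure
  (MUAP shapes, recruitment, firing statistics) is modeled.
* **Envelope** `e(t)`: unit plateau with 0.25 s raised-cosine onset/offset
  ramps, so filter edge transients never dominate a 250 ms segment.
* **Spatial activation** `a_c`: a fixed per-gesture pattern — a circular
  Gaussian bump (σ = 1.2 channels) on the 16-electrode ring plus a 0.05
  baseline, centred at `round(g·16/10)` for gesture `g`. Centres are spread
  around the ring so patterns stay distinguishable (pairwise cosine
  similarity ≤ 0.87) even on the even-indexed 8-channel subset. Per subject,
  activations are multiplied by a fixed log-normal jitter (σ = 0.15),
  a minimal stand-in for electrode placement and anatomy differences.
* **Interference**: a 50 Hz sine of amplitude `powerline_amp` (default 0.2
  relative to the unit-RMS carrier; strong enough to be the dominant
  spectral line, weak enough that the notch restores the signal), a constant
  offset `dc_offset` (default 0.1) and white noise of RMS `noise_rms`
  (default 0.05, i.e. ≈ 26 dB SNR against a fully active channel — a clean,
  well-prepared electrode contact). The powerline phase φ is drawn once per
  recording so no artifact is phase-locked across the dataset.

Protocol defaults mirror the study design: 2000 samples/s, 16 channels,
10 s holds, 3 s rests, 10 repetitions per gesture, 10 gestures, 30 subjects.
All randomness flows from one integer seed through `numpy.random.SeedSequence`
keyed by (subject, gesture, repetition); identical seeds give bit-identical
data.

**What passing tests show** — that the pipeline's arithmetic, filtering and
learning machinery behave as specified on data with the assumed structure.
**What they do not show** — performance on real sEMG, which adds electrode
shift, fatigue drift, cross-talk, inter-day variation and label noise; the
published human-subject accuracies are not reproducible from synthetic data
and are never asserted.

## Noise reduction

* **DC blocker**: first-order (single-pole) Butterworth high-pass, cutoff
  2 Hz. A constant offset decays with time constant 1/(2π·2 Hz) ≈ 80 ms;
  over a 10 s record the residual mean is far below 1 %.
* **Powerline notch**: Butterworth band-stop with stop band 49–51 Hz and
  overall order 4 (prototype order 2 per edge). The designed single-pass
  magnitude is ≤ −20 dB at 50 Hz and ≥ −1 dB at 10 and 100 Hz.
* Both run forward–backward (`sosfiltfilt`/`filtfilt`) by default: offline
  analysis tolerates non-causality, and zero phase keeps window alignment
  intact; a causal mode exists for streaming parity. The chain is DC block
  then notch. The acquisition hardware's 2 Hz–1 kHz analog bandwidth needs
  no software low-pass at fs = 2000 (1 kHz is Nyquist).

## Segmentation and image encoders

Recordings are cut into consecutive **non-overlapping 250 ms segments**
(500 samples); non-overlap guarantees that train and test images never share
samples. The 100 ms window / 50 ms hop slides *within* a segment only, to
form STFT frames.

* **Time-domain images**: each channel is decimated 2× (zero-phase
  anti-alias filter, then every second sample) to 250 columns, rows =
  channels → 16×250 or 8×250. Decimation is the one reading that maps a
  500-sample segment onto 250 image columns; alternatives (a 125 ms span, or
  1000 sps acquisition) are rejected because the protocol fixes 250 ms at
  2000 sps.
* **Spectrograms**: per channel, 4 Hann-windowed frames (200-sample window,
  100-sample hop, no zero-padding at the edges — (500−200)/100+1 = 4) with
  nfft = 256 one-sided → 4×129 linear magnitudes; nfft is the next power of
  two above the window and is what yields 129 = 256/2+1 bins. Channel
  matrices are stacked row-wise in ascending channel order (auxiliary
  channel last) → (4·C)×129.
* **Feature-enhanced spectrograms**: before encoding, an auxiliary channel
  r(t) = max_c s_c(t) — the *pointwise* cross-channel maximum — is appended,
  giving 9/17 channels and 36×129 / 68×129 images. The pointwise reading is
  chosen over per-channel scalar maxima because only a time series can be
  windowed into a spectrogram row block like the other channels.
* **Grayscale**: per-image min–max normalization to [0,1]; a (numerically)
  constant image maps to all zeros; a log-magnitude option exists but the
  default is linear — the simplest faithful pixel scale.

## CNN architectures

Both classifiers are two-block CNNs ending in two dense layers and softmax:

    conv(32, 3×3, stride 1, pad 1) → batch-norm → ReLU → pool₁
    conv(64, 3×3, stride 1, no pad) → batch-norm → ReLU → pool₂
    flatten → dense(128) → dense(n_classes) → softmax

* `spectral_cnn` (32/36/64/68 × 129 inputs): pool₁ = pool₂ = 2×2.
* `time_cnn` (8/16 × 250 inputs): pool₁ spans 3 time columns, pool₂ spans
  2; pooling across *channels* (rows) is impossible here — an 8-row input
  pooled 3× leaves 2 rows and the valid 3×3 convolution then has no output —
  so the time axis, with 250 columns to spare, is the only orientation that
  supports both channel counts.

Pooling is non-overlapping (stride = window) with floor division; rows or
columns that do not fill a window are dropped. The plain and enhanced
spectrogram inputs share one architecture: only the first dense layer's
fan-in (hence its parameter count) differs.

The engine is a small numpy implementation (im2col convolution lowered to
BLAS GEMM, exact max-pool gradients with first-max tie-breaking, batch
normalization with running statistics, Adam). Weights use He initialization
from a seeded generator; float32 throughout.

## Training and evaluation protocol

* Adam, learning rate 1e-3, batch 32, **3 epochs** by default. The
  synthetic classes separate within 2 epochs, and 3 epochs keep the full
  six-condition grid under ten minutes on one CPU core; raise `epochs` for
  harder data. Mini-batches are reshuffled each epoch from the same seed, so
  a fixed seed reproduces loss curves exactly. Inference freezes batch-norm
  statistics, so prediction is deterministic.
* **Split**: whole (subject, repetition) groups are held out (20 % via
  `GroupShuffleSplit`), so the segments of one hold never straddle the
  train/test boundary — the leakage that plagues window-level random splits.
* **Metrics**: confusion matrix with rows = true gesture; per-class accuracy
  = 100·diag/rowsum; a condition's **average accuracy is the unweighted mean
  of per-class accuracies** (this, not pooled sample accuracy, is the
  convention that reproduces the published table's Average row from its
  cells). Display rounding is decimal half-up to one decimal.
* **Conditions**: {time_domain, spectrogram, enhanced_spectrogram} ×
  {8, 16} channels; the 8-channel condition uses electrodes 0, 2, …, 14 —
  every other contact, i.e. evenly distributed ring coverage.
* **Repetitions are individual training examples.** Protocol descriptions of
  this kind of experiment sometimes speak of averaging a gesture's
  repetitions before training; averaging raw sEMG repetitions is ill-defined
  (the carrier is noise-like, so unaligned averages cancel toward zero) and
  would collapse the dataset to one record per gesture. The pipeline instead
  trains on every windowed segment of every repetition, which is the
  standard practice this harness evaluates.

## Problem sizes

The shipped experiments (acceptance script and the heavyweight tests) run
the protocol at 2 subjects × 10 gestures × 3 repetitions with 10 s holds:
2400 segments per condition, ≈ 480 held out. This is the package's
desk-scale default; the full 30 × 10 × 10 protocol is a configuration
change (`SimConfig(n_subjects=30, n_repetitions=10)`), not a code change.

## Known limitations

* The synthetic generator encodes gesture identity mainly in spatial
  amplitude patterns; spectral shape differences between gestures are not
  modeled, which likely flatters all encoders equally rather than ranking
  them as real data would.
* Single-frequency powerline model (no harmonics, no frequency drift);
  adaptive or harmonic-tracking cancellation is out of scope.
* The CNN engine targets these two architectures; it implements exactly the
  layers they need and trains on one CPU core — it is not a general deep
  learning framework.
* Confusion-matrix orientation follows the rows-=-true convention; use
  `EvaluationReport.confusion_transposed()` when comparing against plots
  with predicted on rows.
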