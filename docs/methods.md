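# Methods

`echotherm` estimates tissue temperature during microwave hyperthermia from
texture features of B-mode ultrasound image sequences. This note documents
the models and procedures the package implements, the choices made where the
design was genuinely open, and what the synthetic validation does and does
not demonstrate.

## Problem setting

During microwave heating (2450 MHz ablation needle, ~5 W, 8 min), the speed
of sound and tissue scattering change with temperature, which shows up in
B-mode images as drifts in gray level and texture. A thermocouple provides a
1 Hz ground-truth temperature trace in the 25–65 °C range; the task is to
regress that trace from the image sequence so that, after training,
temperature can be read out non-invasively.

The central modelling idea is that the feature series of a heating run is
genuinely *temporal*: tissue constituents (water, proteins, fats) have
different dielectric constants and heat at different rates, superimposing
shorter heating periods on the main saturating trend. The regression network
therefore detects the dominant periods of the feature series by FFT, folds
the series period-wise into 2D tensors (cycle × phase), and mixes information
within and across cycles with attention.

## Pipeline

1. **Ingestion** (`preprocess.read_sequence`): AVI containers (uncompressed
   8-bit DIB streams via `echotherm.avi`) or directories of image frames;
   color frames are reduced to gray with BT.601 luma weights.
2. **Temporal fusion** (`temporal_fuse`): non-overlapping blocks of
   `round(frame_rate / 1 Hz)` frames are pixel-averaged and rounded half-up
   to 8 bits, aligning the image rate with the thermocouple rate and
   pre-suppressing speckle. A trailing partial block is dropped.
3. **Mean filtering** (`mean_filter`): 3×3 box filter with replicate padding
   (kernel configurable; replication avoids dark-border bias in the mean
   gray level). Output stays in floating point for quantisation downstream.
4. **ROI** (`extract_roi`): a 64×64 patch centered on the temperature probe,
   0-based, half-open; out-of-bounds requests are errors, never clamped.
5. **Texture features** (`glgcm`): see below.
6. **Regression** (`model`, `network`): see below.

## GLGCM texture features

The gray-level gradient co-occurrence matrix is the joint histogram of
quantised gray level and quantised Sobel gradient magnitude at the same
pixel. Gray levels are min–max scaled to {0..N−1} with floor and clipping
(N = M = 16 by default — small enough that 64×64 patches do not produce
sparse matrices); gradients are scaled by their maximum. Two conventions
matter:

* **Quantisation range.** For a single image the natural extrema are the
  image's own min/max. Across a heating sequence, however, per-frame
  normalisation would cancel exactly the temperature-driven drift in mean
  gray level that carries the signal, so `extract_feature_series` quantises
  gray against the fixed 8-bit range (0, 255) and the gradient against the
  sequence-wide maximum. `quantize_pair` records the extrema actually used.
* **Descriptors.** From the normalised matrix H the package computes the
  classical gray-gradient descriptor set (15 with `all_descriptors=True`).
  The five used for modelling are average gray level, gray-level entropy,
  mixture entropy, inertia and inverse difference moment; entropies use the
  natural log with 0·log 0 := 0.

A sixth series-level channel, the **gray-temperature gradient**
(ΔT / ΔAVGL over a 5 s lag, degenerate denominators carrying the previous
value), requires the measured temperature — the prediction target. It is
computed and stored, but excluded from the default model input; a documented
leakage mode (`features.use_gray_temperature_grad`) feeds it to the model for
protocols where a reference sensor is present at training and evaluation.

Channels are ranked by Pearson correlation with temperature
(`pearson_rank`); zero-variance channels are reported as r = 0 with a
warning. On synthetic data the average gray level leads the ranking with
r > 0.95, mirroring its role as the canonical ultrasound thermometry signal.

## Period decomposition

`fft_period_select` computes each channel's DFT amplitude over frequency
indices 1..⌊T/2⌋, normalises every channel's spectrum by its own maximum (so
channels of different units vote equally), averages across channels and
returns the top-k indices, ties breaking toward the lower frequency. Each
frequency f maps to a period p = ⌈T/f⌉.

Heating series are dominated by the saturating trend; its spectral leakage
at the lowest bins would otherwise consume all k slots. The spectrum is
therefore computed on linearly detrended data (the scipy periodogram
convention). The DC bin is always excluded. A series that is constant (or
purely linear) after detrending has no selectable periodicity and raises.

`reshape_2d` zero-pads a length-T series to p·f and folds it so that row =
phase within a period and column = cycle index; `inverse_reshape` is its
exact inverse. Inside the network the same index map is applied to
(batch, T, channels) tensors.

## Regression network

Input windows of 96 s × 5 channels are z-scored with training-set statistics
(targets likewise) and embedded linearly (width 16) with a sinusoidal
positional encoding. Two period blocks follow; each:

1. selects k = 5 periods from the batch-averaged, channel-normalised
   spectrum of its input (selection and amplitudes are treated as constants
   in the backward pass);
2. folds the sequence per period, applies the dual-branch attention module,
   unfolds and truncates the padding;
3. aggregates the k branch outputs with softmax weights over their spectral
   amplitudes, adds the block input (residual) and layer-normalises.

The **dual-branch module** splits the 16 embedding channels in half:

* *Local branch (AttnConv)*: value tokens are mixed by a 3×3 depthwise
  convolution and gated elementwise by tanh-bounded attention weights
  derived from a depthwise-convolved query·key product — high-frequency,
  position-local structure.
* *Global branch*: softmax scaled dot-product attention (2 heads) from every
  flattened 2D position onto keys/values mean-pooled over the period axis
  (one summary token per cycle) — low-frequency global structure at a cost
  linear in the number of cycles. Attention rows sum to 1 by construction.

Branch outputs are concatenated and linearly fused. A per-step linear
bypass from the raw input channels to the output runs in parallel with the
embedding path, and the attention head is zero-initialised: at
initialisation the model *is* its pointwise-linear part, and the period
blocks learn only the temporal residual (the periodic modulations the
pointwise map cannot explain). The bypass is initialised in closed form by
ordinary least squares on the training windows (a two-stage fit), which
removes most of the optimisation burden from the gradient loop.

The default configuration has 2 055 trainable parameters (≈ 0.008 MB in
float32), comfortably inside the ≤ 0.1 MB budget that makes the model
deployable on portable ultrasound hardware. `count_parameters` reports the
exact tally.

All network code runs on a small reverse-mode autodiff engine over numpy
(`echotherm.nn`), gradient-checked against central finite differences in the
test suite. The only deliberate deviations from exact differentiation are
the stop-gradients on period selection and amplitude weights noted above.

## Training and evaluation

* Adam, learning rate 1e-3, weight decay 1e-5, MSE loss, batches of 32
  windows; library defaults keep 1000 epochs and a 7:3 split.
* The split unit is the **experiment**, never the window: time steps within
  one heating run are strongly dependent, and window-level splitting would
  leak across the sets. The split assignment is written to a manifest.
* Early stopping (off by default, patience 50) monitors windows from a
  held-out fold of training experiments. Desk-scale runs in the test suite
  and acceptance script use at most 60 epochs with patience 8, training
  windows at stride 24 and evaluation windows at stride 48 — problem sizes
  chosen so the full study runs comfortably on a single CPU; the network
  converges within these budgets because of the closed-form bypass
  initialisation.
* Evaluation slides windows across each held-out experiment, averages
  per-step predictions where windows overlap, and reports MSE, RMSE and MAE
  overall, per experiment, and per temperature band (25–30, 30–45,
  45–65 °C: the initial transient, mild-hyperthermia and thermo-ablation
  regimes).
* The comparison baseline is a single-layer LSTM with per-step readout whose
  hidden size is the smallest giving at least as many parameters as the
  temporal model, trained with the identical configuration — so the ordering
  comparison is not capacity-bound.

## Synthetic data: what it emulates and what it does not

No ultrasound recordings ship with the package; the generator produces the
study the method assumes:

* **Heating**: T(t) = T0 + (Tmax − T0)(1 − e^(−t/τ)), defaults 25 → 65 °C,
  τ = 120 s, 480 s duration, 1 Hz sampling with 0.05 °C sensor noise. The
  single-exponential form matches the concave saturating rise of
  constant-power heating and keeps a closed form for tests.
* **Echogenicity**: mean gray level = 120 + 0.5·(T − T0) gray/°C. The slope
  is the order of magnitude of published AVGL–temperature couplings in
  phantoms and is configurable.
* **Sub-periods**: sinusoidal gray-level modulations at {6, 20, 48} s with
  amplitudes {1.0, 0.6, 0.4} gray — well separated, all far below the run
  length, resolvable at 1 Hz, and second-order relative to the ~20-gray
  trend rise. These are the "shorter heating periods" the temporal model
  exists to exploit; their frequency indices are the recovery ground truth.
* **Speckle**: multiplicative unit-mean Rayleigh noise (fully developed
  speckle approximation); after 30-frame fusion and 64×64 averaging it
  leaves ~0.2 gray of noise on the patch mean.
* **Spatial texture**: a static mid-frequency pattern (period 16 px,
  amplitude 25 gray) so gradient bins are non-degenerate.
* **Between experiments** the heating side is jittered (T0 ± 0.5 °C,
  Tmax ± 2 °C, τ × U(0.9, 1.1); modulation amplitudes × U(0.8, 1.2), random
  phases), giving pairwise-distinct traces. The measurement model
  (base echogenicity, coupling slope) is held fixed: one calibrated scanner,
  one tissue type. If the sensor model also drifted between runs, absolute
  temperature would not be a recoverable ground truth from gray level alone,
  and the generator's purpose is precisely parameter recovery.

What passing the synthetic study shows: the full chain — frame simulation,
fusion, filtering, texture extraction, period detection, training —
recovers known ground truth (sub-degree held-out RMSE; injected periods
found; temporal model at or above the recurrent baseline). What it does not
show: performance on real tissue, where the AVGL–temperature relation is
nonlinear and saturating above ~60 °C, probes and tissue deform, speckle is
correlated, and scanner settings vary. The synthetic coupling is linear by
construction, so real-data error levels cannot be inferred from these tests.

## Numerical conventions

* Temporal fusion rounds half-up (`floor(x + 0.5)`) to 8 bits.
* Quantisation: floor with clipping to the top level; constant images map to
  level 0; all-zero gradients map to level 0.
* Entropies: natural log, 0·log 0 := 0.
* Degenerate gray-temperature-gradient denominators (|ΔAVGL| < 1e-9) carry
  the previous value, 0 at the series start; the final `lag` positions carry
  the last computed value.
* Period selection ties break toward the lower frequency; a spectrum peak
  below 1e-9 × the series scale is treated as silence.
* The pseudocolor map slides the ROI on a stride-16 grid, predicts a
  temperature series per tile and renders snapshots on a fixed 25–65 °C
  scale — a rendering convention, not a calibrated spatial reconstruction.

## Known limitations

* The gray-temperature-gradient channel is only usable when measured
  temperatures exist; autoregressive feeding of prior predictions is not
  implemented.
* Period selection inside the network is batch-global (one period set per
  batch); per-sample selection would be slower and complicate batching.
* The backward pass ignores the dependence of period selection and
  amplitude weights on the parameters (stop-gradient).
* Training is single-threaded numpy; the defaults are sized for CPUs, not
  for large-scale studies.
* The AVI reader handles only uncompressed 8-bit DIB streams; compressed
  video must be exported to frame directories first.
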