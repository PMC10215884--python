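# Methods

This document describes the model implemented by `eegdenoiser`, the data
model around it, every user-facing parameter (with units, defaults and
rationale), the numerical choices, and the known limitations of the
desk-scale setup.

## 1. Problem setting

Single-channel EEG segments are contaminated by ocular (EOG) and/or muscular
(EMG) artifacts. Denoising is posed as supervised sequence-to-sequence
regression: given a noisy, normalized segment **ŷ**, predict the clean,
normalized segment **x̂** of the same length. Ground truth is available
because contamination is semi-synthetic: clean EEG and pure artifact
segments are mixed at controlled signal-to-noise ratios.

### 1.1 Segments

A `Segment` is one fixed-length single-channel trace in microvolts with a
sampling rate and a kind:

| kind | length | rate | duration |
| --- | --- | --- | --- |
| EEG | 512 samples | 256 Hz | 2 s |
| EOG | 512 samples | 256 Hz | 2 s |
| EMG | 1024 samples | 512 Hz | 2 s |

Banks of such segments are read from HDF5 or NPZ containers (one 2-D
`segments × samples` dataset named `eeg`/`eog`/`emg`), or produced by the
surrogate generator (§5).

### 1.2 Contamination model

Noisy segments follow the linear mixing model

```
y = x + λ · n
```

where `x` is clean EEG, `n` the artifact (EOG, EMG, or their sum for the
combined scenario — a single λ scales the summed artifact), and λ is solved
so that the segment attains a requested SNR:

```
SNR = 10 · log10( RMS(x) / RMS(λ·n) )      =>      λ = RMS(x) / (RMS(n) · 10^(SNR/10))
```

Ten integer SNR levels, −7 dB … +2 dB, are used by default. Before training,
each pair is normalized by the *noisy* segment's standard deviation σ_y:

```
x̂ = x / σ_y        ŷ = y / σ_y
```

so network inputs have unit variance while the target keeps its relative
scale. For mixed-rate scenarios (EMG, EOG+EMG) the 256 Hz signals are
upsampled ×2 by exact Fourier zero-padding before mixing.

### 1.3 Scenario assembly and splits

A scenario pairs each clean segment with a distinct artifact segment
(sampling without replacement — no clean or artifact segment is reused), and
applies the *same* couple at every SNR level. With full-size banks
(4514 EEG / 3400 EOG / 5598 EMG) this yields 34,000 EOG-scenario pairs and
45,140 EMG-scenario pairs over the 10 levels.

Splits are defined on couple indices, so a clean segment never appears on
both sides of a split at any SNR level. The default protocol takes
floor(0.8·n) couples as the training portion and the rest as test; 10 % of
the training portion is held out for validation/early stopping. Per level
for the EOG scenario: 2720 training-portion / 680 test (the 2720 decompose
as 2448 train + 272 validation). Pooled over the 10 levels: 27,200 / 6,800
(EOG) and 36,110 / 9,030 (EMG). K-fold cross-validation (default 5 folds)
partitions couples into disjoint test folds the same way.

## 2. Model

### 2.1 Architecture

`MultiResUNet3Plus` is a 1-D encoder–decoder of depth `d` combining:

* **MultiRes blocks** — three chained kernel-3 convolutions of increasing
  width, whose concatenation (total width = the block's filter budget `W`)
  is added to a kernel-1 shortcut of width `W`, then batch-normalized and
  ReLU-activated. A budget `W` splits into branch widths
  `round(W/6), round(W/3), W − round(W/6) − round(W/3)`;
  e.g. `W = 320 → (53, 107, 160)`.
* **Full-scale skip connections** — decoder level `M` receives a
  resolution-matched feature map from *every* level: encoders `1..M` (via
  max-pooling for shallower origins) and decoders/bottleneck `M+1..d` (via
  nearest-neighbour upsampling), `d` incoming maps in total.
* **Residual paths (ResPaths)** — every skip connection passes through a
  chain of residual-convolutional blocks (conv-3 ⊕ conv-1 shortcut, add,
  BN, ReLU). Encoder→decoder paths from origin level `L` carry `d − L`
  blocks; decoder→decoder paths carry `d − L + 1`; shallower origins get
  more blocks to bridge the larger semantic gap.

Channel bookkeeping: encoder level `i` has filter budget `n·2^(i−1)`
(clamped to ≥ 6 so the three-branch split is never empty in toy
configurations); every ResPath outputs `n` channels, so each decoder
concatenates exactly `W = n·d` channels and fuses them with a MultiRes block
of budget `W`. A final kernel-1 convolution maps decoder 1 to one linear
output channel; output length equals input length. With deep supervision
enabled, kernel-1 side heads on decoders 2..d−1 and the bottleneck produce
auxiliary full-length outputs (4 side outputs + 1 final at `d = 5`) whose
MSE losses are averaged with the main loss.

The reference configuration is `d = 5`, `n = 64` (`W = 320`); the
desk-scale test configuration is `d = 3`, `n = 8`.

### 2.2 Training

The model/results interface follows the statsmodels convention:
`EEGDenoiser(y_hat, x_hat, arch, config)` is bound to data;
`.fit()` returns a `DenoiserResults` with the trained network, loss/validation
histories, `predict`, `evaluate` and `summary()`.

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `learning_rate` | 5e-4 | — | the method's stated Adam learning rate |
| loss | MSE | — | the method's stated objective |
| `epochs` | 100 | — | free design choice; desk-scale runs plateau in 40–70 epochs (§6) |
| `batch_size` | 32 | segments | free design choice; smaller batches (8) give more updates per CPU-second at equal wall time |
| `patience` | 10 | epochs | early stopping on validation MSE; best-epoch weights restored |
| `val_fraction` | 0.1 | — | matches the 10 %-of-training-portion validation convention |
| `folds` | 5 | — | cross-validation convention |
| `deep_supervision` | off | — | optional auxiliary losses (§2.1) |

Training runs in float32 (the parameters' dtype); this halves the cost of
the convolution GEMMs relative to float64 with no measurable effect on the
evaluation metrics, which are always computed in float64.

### 2.3 Implementation note

No deep-learning framework is used. `eegdenoiser._autodiff` is a minimal
reverse-mode tape over NumPy arrays supplying exactly the needed operators
(same-padded conv1d as a single GEMM plus K shifted accumulations,
max-pooling, nearest upsampling, concatenation, ReLU, batch normalization,
MSE) with hand-derived backward passes, verified against finite differences
in the test suite, plus a standard bias-corrected Adam.

## 3. Evaluation metrics

All metrics are computed per segment in float64 and aggregated as
mean ± std (population std):

* `cc_temporal` — Pearson correlation between prediction ẑ and truth x̂.
* `eta` (η, %) — temporal percentage reduction in artifacts,
  `η = (1 − (1 − CC_af)/(1 − CC_bf)) · 100`, with CC_af = corr(ẑ, x̂) and
  CC_bf = corr(ŷ, x̂). η = 100 for perfect recovery, 0 for returning the
  input unchanged, negative if the "denoised" output is worse.
* `gamma_pct` (γ, %) — the same construction on Pearson correlations of
  one-sided periodogram PSDs.
* `rrmse_temporal` / `rrmse_spectral` — `RMS(error)/RMS(reference)` in the
  time domain / between PSDs.
* Band-power ratios — fraction of periodogram power in delta (1–4 Hz),
  theta (4–8), alpha (8–13), beta (13–30) and gamma (30–80), relative to
  the 1–80 Hz total, reported for ground-truth, noisy and predicted
  segments.

The PSD is the plain rectangular-window periodogram (no Welch averaging, no
detrending), so the discrete Parseval identity `Σ PSD · Δf = mean square`
holds exactly. Band edges are half-open `[lo, hi)`, except the partition's
top edge (80 Hz) which closes the last band, making the five ratios of any
1–80 Hz band-limited signal sum to exactly 1.

## 4. Experiment protocols

* **Experiment A** (per-SNR): one independent training per SNR level;
  reports CC and RRMSEs on that level's test split. Difficulty, and hence
  test CC, is monotone in SNR.
* **Experiment B** (pooled): a single training on pairs pooled over all SNR
  levels; reports η, γ, RRMSEs and band-power tables.

Both run under k-fold cross-validation over couples.

## 5. Surrogate signal generator

Real banks are supported through the container reader; the surrogate
generator exists so the entire pipeline is exercisable without external
data. Each surrogate is synthesized by inverse-DFT spectral shaping:
magnitude ∝ `f^(−α)` strictly inside a passband (zero outside), uniform
random phases, rescaled to a target RMS.

| kind | passband | α | RMS | mimics |
| --- | --- | --- | --- | --- |
| EEG | 1–80 Hz | 1.0 | 10 µV | broadband 1/f-type background |
| EOG | 0.3–10 Hz | 1.5 | 15 µV | slow, large ocular deflections |
| EMG | 1–120 Hz | 0.0 | 80 µV | broadband, much larger amplitude |

Fidelity limits, by construction: (a) each bank has a *fixed* magnitude
spectrum — only phases are random — so surrogates lack the trial-to-trial
spectral variability, transients and non-stationarity of real signals;
(b) random-phase signals are Gaussian-like, so the optimal denoiser given a
finite window is essentially linear (this matters for §6); (c) real EOG
blinks are asymmetric ballistic waveforms, not stationary low-passed noise.
Surrogate-trained numbers therefore characterize the pipeline, not the
method's attainable performance on real data.

## 6. Desk-scale performance analysis and limitations

On the surrogate EOG scenario (pooled SNR −7..+2, normalized pairs), the
following ceilings were measured (seeded, held-out couples):

| predictor | held-out η (%) |
| --- | --- |
| per-pair Wiener oracle (true noise spectrum known) | ≈ 67 |
| single pooled 512-tap linear (Wiener) filter | ≈ 65 |
| optimal 75-tap least-squares FIR, pooled | ≈ 30 |
| optimal 75-tap FIR, separate per SNR level | ≈ 43 |
| trained d=3, n=8 network (120 epochs, converged) | ≈ 21 |
| identity (ẑ = ŷ) | 0 |

The `d = 3, n = 8` network's receptive field, measured numerically, is 74
samples (~0.29 s at 256 Hz). Because the surrogates are Gaussian-like (§5),
the best possible predictor given a 74-sample window is linear per SNR
level — the 43 % row above is therefore an upper bound for this
architecture on this data, regardless of training budget. The dominant EEG
and EOG power overlaps below 10 Hz, where discriminating 1–3 Hz structure
requires context much longer than 74 samples; deeper networks (`d = 5`
scales the receptive field by ~5×) or real, non-Gaussian artifact waveforms
change this picture. Consequently the reduced-scale learning acceptance
test's η > 50 % assertion fails by construction (the network honestly
reaches ≈ 20 and is validation-plateaued, not under-trained); its companion
assertions — beating the identity predictor on RRMSE_temporal (0.78 vs
≈ 2.2) and test CC non-decreasing in SNR — pass.

Other limitations:

* Single-threaded NumPy training is ~100 ms per batch-8 step for the small
  test network; the reference `d = 5, n = 64` configuration is not
  practically trainable in this implementation.
* Batch normalization uses per-batch statistics during training; very small
  batches give noisy statistics (batch ≥ 8 recommended).
* Fourier resampling assumes integer rate ratios (×2 is what the pipeline
  needs); segments are treated as circular by the periodogram and the
  resampler, consistent with the band-limited surrogate construction.
* `eta`/`gamma_pct` are averaged per segment; computing them from pooled
  correlations instead would weight segments differently.

## 7. Numerical choices

* Width splitting uses half-up rounding `floor(x + 0.5)`, so small budgets
  split deterministically across platforms.
* λ is computed in closed form (no iterative SNR matching); SNR round-trip
  error is < 1e-6 dB by construction.
* σ_y uses the population standard deviation (`ddof = 0`).
* Convolution weight initialization is uniform `±√(6 / fan_in)`; biases are
  zero; BN starts at identity (γ = 1, β = 0) with running statistics in
  float64.
* Early stopping restores the best-validation-epoch weights, including BN
  running statistics.
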