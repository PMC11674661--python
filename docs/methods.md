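# Methods

This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic data can and cannot show.

## Synthetic EEG model

Each trial is a 2 s, 64-channel, 160 Hz epoch in microvolts, built as
background + class signal + artifacts.

**Background.** Per-channel pink (1/f) noise plus a spatially
correlated component: 12 dipole-like pink sources mixed into the
montage through a smooth Gaussian-of-distance mixing matrix (width 0.6
on the unit sphere).  The mixture is scaled to ~10 uV RMS.  The
correlated part is what gives the mean-correlation channel criterion
and the ICA step something real to work with.

**Class signal.** Three amplitude-modulated sinusoidal carriers drawn
inside `signal_band` (default 8–13 Hz, the mu band) with a slow (<1 Hz)
positive envelope, projected through a class-specific scalp map:
Gaussian bumps (width 0.55 chord units) centred on C4 for left-hand, C3
for right-hand, C3+C4 for both-hands, Cz for both-legs — the classic
contralateral motor-strip layout.  The signal is scaled per epoch so
that its channel-mean power is `snr` times the background power; `snr=0`
injects nothing and is verified to carry no class information.  This is
an amplitude-topography code, not a biophysical forward model: it is
separable by spatial band-power learners (exactly what the tested CNNs
can extract), which is all the study design requires.

**Subject variability.** `subject_variability` scales (i) a global gain
jitter, (ii) Gaussian jitter of the topography centres, and (iii)
per-channel multiplicative map noise.  At 0 all subjects share
topographies (transfer learning has nothing subject-specific to learn);
at ~1 a pooled model generalises poorly until fine-tuned.

**Artifacts.** Blinks: 300–500 ms biphasic (sine-in-Hann) pulses,
80–150 uV, frontally peaked (Gaussian map around Fpz, width 0.45).  EMG:
0.2–0.6 s bursts of >25 Hz high-passed noise, 25–60 uV, on a tight
channel cluster.  Globally bad channels (Poisson count, default mean 1
per subject): dead (x0.01) or noisy (+20x background, nearly white).
Per-epoch bad channels: +15x pink noise on one channel.  Line noise:
common-phase 50 Hz with per-channel gain spread.  Every injection is
written to the `GroundTruth` record.

**Determinism.** All draws come from
`default_rng([seed, subject_id])`; identical (config, seed) is
bit-identical.

What the generator does **not** emulate: realistic ERP morphology,
volume-conduction forward physics (BEM), non-stationary drifts,
electrode impedance changes, or realistic cross-trial autocorrelation.
Passing tests therefore demonstrate the pipeline's mechanics and
statistical behaviour, not clinical-grade performance on real EEG.

## Filtering

5th-order Butterworth, designed as second-order sections (stable at the
0.1 Hz edge on 160 Hz data) and applied forward–backward, so the phase
is zero and the effective magnitude order doubles.  Epochs are filtered
as one concatenated pseudo-continuous signal per channel with
even-reflection padding: a 0.1 Hz edge settles over thousands of
samples, and short odd-reflection padding (the scipy default) lets the
startup transient dominate a 2 s epoch.  `band=None` is the identity
("no filtering" arm).  No 50 Hz notch is applied by default; the study
design varies pass bands instead.

## FASTER

Four sequential steps; all thresholds are Z > 3 (two-sided) computed
across the item population of the current recording only.

* Channel criteria: variance, mean absolute Pearson correlation with
  all other channels (computed on the concatenated epochs), and the
  Hurst exponent.  Non-finite parameters (dead channels) are always
  flagged.
* Epoch criteria: channel-averaged amplitude range, deviation of the
  epoch's channel means from the channel grand means, variance.
* ICA: fast-ICA with the logcosh (tanh) contrast, as many components
  as retained channels, seeded; component criteria are max |corr| with
  the ocular-proxy channels {Fp1, Fpz, Fp2, AF7, AF8} (the cap has no
  EOG leads), kurtosis, mean gradient of the log power spectrum above
  8 Hz, Hurst exponent, and median absolute time-gradient.  Rejected
  components are zeroed and the data back-projected.  Tolerance is
  1e-3 with up to 1000 iterations and one seed retry; if the fixed
  point is not reached (typical when no distinctly non-Gaussian source
  exists) the last iterate is used and `converged=False` recorded —
  the reconstruction identity holds regardless.
* Per-epoch channel criteria: variance, median gradient, amplitude
  range, deviation from the channel's own mean, Z-scored across
  channels within each epoch.  Flagged channels (global and per-epoch)
  are repaired by spherical-spline interpolation and the result is
  re-referenced to the scalp average.

Globally bad channels are excluded from the ICA fit and interpolated
afterwards; the across-subject fifth step of the original algorithm is
out of scope by design.

**Hurst estimator.** Rescaled-range over log-spaced window sizes
(16 … n/2, 12 sizes) with the Anis–Lloyd–Peters small-sample expectation
subtracted before the slope fit (H = 0.5 + slope).  This debiasing makes
white noise read 0.50 ± 0.03 at n = 8192; without it the estimate sits
near 0.56 and drifts with n.

**Spherical splines.** Perrin-style: g(x) expanded in 50 Legendre terms
with stiffness m = 4 and diagonal regularisation 1e-7; the constant is
carried by an explicit intercept, so constant fields are reproduced
exactly.  The small regulariser keeps the interpolation bias low on
smooth fields (worst-case error on degree-≤2 harmonic fields is at the
below-equator electrodes T9/T10, ~9 %) while still suppressing the
near-singular modes of the 63-electrode Gram matrix.

## Dense grid and cropping

The shipped 9x7 table was derived by azimuthal-equidistant projection of
the unit-sphere positions, slicing the 63 electrodes (Iz dropped) into 9
anterior-to-posterior rows of 7, and ordering rows left-to-right.  The
table is a versioned CSV so the representation cannot drift; a test
asserts the derivation still reproduces it and that grid-adjacent
electrodes are closer in 3-D than random pairs.  Epochs are taken as
[0, 2] s from cue onset.  Crop offsets are quantised to whole samples
(0.1 s → 16 samples); with 1 s windows in 2 s epochs this yields 11
crops, and crops always inherit their parent epoch's group id.

## Decoders

All five architectures run on an in-package numpy engine (im2col 2-D
convolutions, shifted-matmul 3-D convolutions, depthwise/separable
convolutions, batch-norm, ELU/square/log, average pooling, dropout,
Adam, softmax cross-entropy), float32, deterministic per seed.  Backprop
is verified against central differences to 1e-6 in float64.

* **Conv2D Net** — L2-normalised input; 3x3x(depth) kernels, 32→64→128,
  the first layer spanning the whole time axis (time is collapsed after
  layer 1); dense 1024 → 64 → softmax.  ELU between layers (the
  activation is not pinned by the design; documented choice).
* **Conv3D Net** — 32 kernels per layer, (1,1,30) then twice (2,2,40),
  batch-norm + ELU between convolutions, dense 32 → 32 → softmax.
  Spatial padding 'same', temporal 'valid' (so T ≥ 108).
* **Multi-branch Conv3D** — three branches of two Conv3D layers and
  three dense layers (last = class count), outputs summed then
  softmaxed.  The branch kernel sizes (temporal scales 10/20, 30/40,
  50/60 at 16 kernels) are a reconstruction, exposed as configuration.
* **EEGNet** — temporal conv of length fs/2 (80 taps at 160 Hz), F1=8;
  depthwise spatial conv over all channels with D=2; separable conv
  F2=16; pooling 4 then 8; dropout 0.5; dense softmax.
* **Shallow ConvNet** — temporal conv (40 x 25), spatial conv over all
  channels, square, mean-pool (75, stride 15), log, dropout, dense
  softmax — a learned band-power extractor.  All hyperparameters are
  configurable; defaults follow the original publication.

Training uses Adam (lr 1e-3), categorical cross-entropy, batch 32 —
none of these is pinned by the study design; all are configurable.
Early stopping monitors validation loss and restores the best weights.

## Regimes and bookkeeping

Simple: stratified 5-fold CV repeated 3 times → 15 accuracies per
subject/network; seeds derive from (master seed, subject, repeat, fold).
Transfer: subjects partitioned into 10 held-out groups (each subject
exactly once); per iteration the network pre-trains on the pooled
remainder (20 % validation split, patience 15), then each held-out
subject's clone fine-tunes all layers for 15 epochs without validation
and is evaluated on the subject's CV test folds; the frozen pre-trained
model is evaluated on the same folds for the paired contrast.  Cropped:
folds are computed on parent epochs and expanded to crops (asserted
leak-free); accuracy is per crop — per-epoch vote aggregation is
available but not the default, which is the minimal reading of the
design.  Filtering and FASTER are applied to the whole subject recording
before any split: a deliberate global-preprocessing choice, so FASTER
statistics never adapt to a particular fold.

## Statistics

Across subjects: two-sided Wilcoxon signed-rank on paired accuracies
(zeros dropped; all-zero differences → p = 1).  Within subject: both
samples pass Shapiro–Wilk at α = 0.05 → Welch t-test, otherwise
Mann–Whitney U; a significant result scores sign(mean difference), else
0.  α = 0.05 throughout; no multiple-testing correction across subjects
(by design — the scores are descriptive, not confirmatory).  Cumulative
subject scores are bounded by ±(networks x runs); ranking is a stable
descending sort.

## Desk-scale study sizes

The learning studies in `studies.py` (used by the analysis drivers, the
acceptance script, and the test suite) keep the full data structure —
64 channels, 160 Hz, 2 s epochs, 4 balanced classes — and shrink only
sample counts and model width: band recovery trains a reduced Shallow
ConvNet (8 temporal / 8 spatial filters, 25 epochs) on 90/30 trials of
one high-SNR subject; the transfer study uses 10 subjects x 32 trials,
2-fold evaluation, 10 pre-training epochs.  These sizes give wide
margins on the tested directions (in-band ≈ 1.0 vs off-band ≈ chance;
fine-tuned − frozen ≈ +0.25 with exact-test p < 0.005) while completing
in minutes on one CPU.

## Known limitations

* The numpy engine targets clarity and determinism, not speed; the full
  105-subject grid of a real study is outside its scope.
* EDF export is not provided (no writer backend); the internal
  npy+JSON container and FIF export cover interchange, and EDF reading
  is supported for the public motor-imagery dataset.
* The multi-branch kernel sizes and the Conv2D Net activation are
  reconstructions where the design is under-specified; both are
  configuration, not constants.
* Per-epoch interpolation repairs channels inside epochs that survived
  rejection; an epoch with many bad channels is rejected wholesale
  first, so pathological epochs never reach the spline.
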