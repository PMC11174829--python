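# Methods

## Windows and labels

Recordings are sliced into non-overlapping 356-sample windows (the
canonical model input; ≈2.05 s at the Bonn rate of 173.61 Hz). 356 is the
primary parameter and window-seconds a derived one: the published model
geometry (5×356 input, 256×356 / 356×4 / 256×11×18 stream outputs) is
internally consistent only at 356 samples, whereas "2 s at 173.61 Hz"
would give ≈347. A 4097-sample Bonn recording yields 11 windows. New Delhi
1024-sample recordings are covered with hop 334 (3 windows each,
near-full coverage, no resampling — the network is shape-aware, not
rate-aware). Bonn subsets Z/O/N/F map to interictal (0) and S (synonym E)
to ictal (1); New Delhi pre-ictal is excluded from the binary task by
default. Splitting is window-level; windows from one recording can land in
different splits, which matches the stated protocol but can flatter
absolute accuracies relative to recording-level splits.

## Feature matrix

All five rows are derived from the once-z-scored raw window (per-window
standardization is on by default; it removes the large scale differences
between scalp and intracranial recordings and between datasets). Amplitude
and phase rows are the full two-sided spectra so all rows share length N;
phase at near-zero-magnitude bins is numerically meaningless and is passed
through as computed (tests exclude such bins, and compare phases modulo
2π). Differences use the forward forms with zero-padded tails (1 element
for the first difference, 2 for the second) to preserve alignment with the
raw row; zero is neutral there. The optional band-pass utility
(0.5–70 Hz) is implemented as an FFT-domain mask with raised-cosine
transitions — exactly zero-phase and length-preserving, and free of the
multi-second start-up transients an IIR high-pass develops at sub-hertz
edges — and is off by default.

## STFT

Hann window (periodic), 64 samples, hop 16, one-sided magnitudes, no
centring or padding: a 356-sample window gives a 33×19 spectrogram. This
recipe was chosen jointly with the 2D stream's reduction (max-pool (3,1),
then a valid (1,2) convolution) so the stream ends at exactly 256×11×18.

## Network

Channel progressions 5→64→128→256 (1D) and 1→64→128→256 (2D) are the
conventional doubling choice; only the final 256 is fixed by the target
shapes. Kernels are 3 / 3×3 with symmetric padding so lengths survive each
block. The residual branch is a 1×1 convolution (5→256) of the raw
feature matrix, added after BN + ReLU of `y1` — the stated order of
operations. Channel attention is squeeze-and-excitation (global average →
C/16 bottleneck → ReLU → sigmoid gate), placed after the third block of
each stream; the attention design and placement are our choice, since only
the module's presence is prescribed. The LSTM head keeps all 356 hidden
states (hidden size 4), matching the 356×4 output. The classifier is a
single fully connected layer (no dropout). Batch norm uses batch
statistics during training and running statistics (momentum 0.1) at
evaluation.

The layers, backpropagation and Adam are implemented directly in NumPy:
convolutions via im2col and BLAS matrix products, float32 parameters by
default (float64 available per layer and used in oracle tests). Every
layer's gradient is verified against central finite differences, and
forward passes against brute-force cross-correlation / scalar-recurrence
oracles.

## Training protocol

Loss, optimizer and schedule are not dictated by the architecture; we use
cross-entropy with Adam (lr 1e-3, β = 0.9/0.999, batch 32) for 30 epochs
by default, with the best-validation-accuracy checkpoint retained. Splits
are stratified 8:1:1 with largest-remainder apportionment per class.
Cross-validation defaults to 10 folds; fold i is the test part, fold
i+1 (mod k) the validation part, the rest training, with a fresh seeded
model per fold; the summary is the plain arithmetic mean of fold
accuracies. All randomness (generation, splits, initialization, batch
order) descends from explicit integer seeds; on one machine a repeated run
reproduces the loss history bitwise. A non-finite loss aborts with a
diagnostic rather than continuing.

Zero-denominator metrics (no predicted positives, or no true positives)
are reported as 0 with a `degenerate` flag instead of raising, so
degenerate folds don't abort a suite.

## Synthetic generator

Interictal windows are sums of five sinusoids, one per conventional EEG
band (delta 0.5–4, theta 4–8, alpha 8–12, beta 12–30, gamma 30 Hz up to
0.45·fs), with per-window uniform random frequency and phase, default
band amplitudes (1.0, 0.8, 1.0, 0.5, 0.2) emphasizing delta/alpha, plus
Gaussian noise (sd 0.5 — moderate against unit band amplitudes). Ictal
windows add a periodic spike-and-wave train at 3 Hz (the classic absence
morphology): per period one narrow positive half-sine spike (width
1/(8·rate) s) followed by a slow opposite-sign half-wave at half the spike
amplitude, scaled so the spike peak is 4× the background RMS. The
generator reproduces exactly the property the classifier exploits —
excess low-frequency power and stereotyped morphology during seizures —
and nothing else: no 1/f background, no artifacts, no inter-subject
variability, no non-stationarity. Passing tests therefore demonstrate that
the pipeline learns a separable two-class spectral/morphological contrast
end to end; they do not certify clinical-grade performance on real EEG,
which must be assessed on the public datasets via the CLI.

A 2–4 Hz band-power threshold alone separates the default classes with
≥90 % accuracy; this separability floor is asserted in the tests so that
training-based checks measure optimization, not luck.

## Problem sizes used by the test suite

The NumPy implementation runs the full canonical architecture at roughly
60 ms per window-iteration on one CPU core, so the suite exercises the
identical pipeline at reduced size as the package's own desk-scale
choice: the end-to-end acceptance check trains on 100 windows (50 per
class, seed 7) for 5 epochs on each of 3 seeds (threshold ≥0.95 test
accuracy per seed, unchanged); the 4-variant ablation suite uses 60
windows and 4 epochs; protocol and cross-validation checks run micro
trainings (1 epoch, often the conv-only variant) because their assertions
are structural. Library and CLI defaults remain the full-scale conditions
(200 windows per class, 30 epochs, 10 folds).

## Known limitations

* Single-channel only; no montage handling, artifact rejection or
  wavelet features.
* Binary head only (interictal vs ictal); New Delhi pre-ictal data can be
  loaded but is not part of the default task.
* Window-level splitting (see above) is the protocol reproduced here, not
  a recommendation for clinical evaluation.
* Training on the full public datasets at 30 epochs is CPU-hours-scale in
  this pure-NumPy implementation; the architecture is small, but no GPU
  path is provided.
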