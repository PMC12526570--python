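# Methods notes

This note records the modelling assumptions, the defaults that matter, what
the synthetic generator does and does not emulate, and the choices made
where the design was genuinely open.

## Problem and model

The task is four-class rhythm classification (bradycardia, tachycardia,
ventricular tachycardia, ventricular flutter/fibrillation) from a single
PPG channel, cut into 10 s windows. The classifier is a dual-branch
network: a convolutional/recurrent time branch with a cross-scale
interactive attention block, a frequency branch operating on a spectral
self-similarity matrix, and an attention-based fusion head. The
architectural contracts (scaled dot-product attention, multi-head
projection and concatenation, residual layer normalization, the Welch
estimator with window-energy normalization U = (1/L)Σw², arctan
compression, S = X·Xᵀ, the weight-aware stride rule with S_ref = 250,
S_min = 125, S_max = 500, β = 1, and the Pre/Sen/Spe/F1/Acc formula set)
are implemented literally and each is pinned by an oracle test.

The network and its training loop run on a compact numpy reverse-mode
autodiff engine (`ppgrhythm.nn`): tensors record backward closures, and
LSTM/convolution/pooling are fused primitives with hand-written,
batch-vectorized backward passes. Every gradient path is checked against
central finite differences in `tests/test_nn.py`. Float64 is used
throughout; determinism is exact given the seeds (weight init, batch
shuffling and dropout masks all derive from explicit generators).

## Sampling rate

No sampling rate is stated for the source waveforms; 250 Hz is inferred
from the stride rule's reference stride of 250 samples being described as
1 s. All rates are configurable, and window lengths are always computed as
`round(window_s * fs)`.

## Synthetic data: what it emulates and what it does not

`synth` generates records whose *rhythm semantics* match the four class
definitions:

* pulsatile classes: beats are a systolic Gaussian plus a delayed, smaller
  dicrotic Gaussian; heart rate is drawn uniformly per record from
  (25–38) bpm for bradycardia, (142–180) for tachycardia and (110–180) for
  VT; beat-to-beat interval jitter is 3 % (8 % for VT, rhythm
  irregularity); per-beat amplitudes jitter lognormally at 5 %. VT uses a
  wider, nearly notch-free template (width fraction 0.20 vs 0.10, dicrotic
  amplitude 0.05 vs 0.35), so VT vs tachycardia is a morphology problem,
  not a rate threshold.
* VF: an amplitude-modulated sinusoid whose instantaneous frequency drifts
  inside 4–7 Hz (clipped random walk), with no pulse train — matching the
  spectral description of fibrillatory waveforms without claiming
  hemodynamic fidelity.
* every record gets a 0.05 Hz sinusoidal baseline wander at 30 % of the
  pulse amplitude and additive Gaussian noise at 2 % (defaults), both
  removable by the conditioning chain.

Not emulated: motion artifacts, sensor dropouts, inter-subject morphology
variation, asystole, or mixed rhythms within a record. Passing the
end-to-end test therefore demonstrates that the pipeline and model are
correct and trainable, **not** that the reported clinical-grade accuracy
transfers to real recordings; on this generator the classes are separable
by construction (a two-feature linear oracle reaches ≥ 95 %, which is why
the end-to-end bar of 90 % is meaningful but attainable).

## Preprocessing defaults

* Bandpass: 4th-order Butterworth, 0.05–30 Hz, applied forward-backward
  (zero phase) as second-order sections with reflect padding. The 0.05 Hz
  edge has a transient of tens of seconds, so the pad length is
  `3·fs/band_low` samples (capped by the signal length).
* Moving average: 0.04 s (10 samples at 250 Hz) — no length is specified
  upstream; this smooths noise without flattening the dicrotic notch.
  Centered window; edge windows shrink symmetrically; even counts are
  widened by one sample.
* Baseline correction: wavelet approximation (db4, level chosen so the
  approximation band is below 0.5 Hz — level 8 at 250 Hz) computed on the
  1 s moving-average trend of the signal (so pulse transients do not leak
  into the drift estimate, and with reflect padding so decomposition edge
  effects stay outside the record), plus a cubic spline through 1 s-spaced
  medians of the residual trend (4 s moving average). Returned signal is
  input minus drift.
* Min–max scaling to [0, 1] per record, before windowing; per-window
  renormalization is deliberately not applied. Constant inputs raise a
  degenerate-signal error instead of emitting NaN.

## Splitting and augmentation

Records are split 6:2:2 per class (shuffle, largest-remainder rounding,
repair so every split is populated whenever a class has ≥ 3 records)
*before* any window is cut, so no record contributes windows to two splits.
The stride rule uses inverse-frequency class weights normalized to mean 1
(a balanced dataset then reproduces the reference stride exactly);
rounding is half-away-from-zero before clipping. Strides are computed from
training-split counts only; validation windows use the fixed reference
stride and test windows are non-overlapping (stride = window), keeping
evaluation independent of the augmentation policy. Both evaluation
stridings are configurable since the upstream protocol does not pin them.

## Spectral features

Welch defaults: L = 256 (~1 s), 50 % overlap, Hann taper — a 10 s window
yields K = 18 averaged segments, enough for the variance-reduction property
asserted by Monte-Carlo test. The self-similarity matrix is built from
band-by-segment energies: the one-sided spectrum is partitioned into B = 32
(default) contiguous equal-width bands, band energies per segment are
arctan-compressed, and S = X·Xᵀ. Compression precedes the Gram product, so
the ranking preserved is that of band energies and any single spike's
influence is bounded. The alternative reading — tokens directly over PSD
bins — is available via `ssm_mode="bins"`.

## Architecture defaults and the parameter budget

Layer widths are not published; the defaults (stem 32 filters k=7,
max-pool 16, residual blocks 32→64 k=5, CSIA d_model 64 with 4 heads,
BiLSTMs 64/32, B=32 bands, transformer d_model 32 with 4 heads and FFN 64,
1×1 conv to 32, frequency BiLSTM 32, common fusion width 64,
channel-attention reduction 4, FC 128→4) were chosen once so that the
total trainable count, 1,541,796, stays within ten percent of the 1.46 M
design budget (the two published totals, 1,465,175 and 1,461,904, disagree
with each other; no exact match is attempted). The max-pool of 16 sets the
fused sequence length (156 tokens for 10 s at 250 Hz); the flatten + first
FC layer dominates the count. The memory identity 1,465,175 × 4 bytes =
5.59 MB uses the MiB convention.

Open points resolved as package choices: the value path of the cross-scale
attention is GAP(stem features) → linear projection → broadcast over time
(the "reconstruction" is stated, the broadcast is inferred); the encoder
keeps a standard FFN sublayer (disable with `ffn=false` for the literal
minimal reading); alignment upsamples the shorter branch linearly by an
integer factor and zero-pads the remainder; self-attention operates on the
channel-concatenated aligned pair projected back to the common width; the
fusion gate is a single-sigmoid convex gate z⊙a + (1−z)⊙b. Ablation
switches (`use_residual`, `use_csia`, `use_time`, `use_freq`,
`use_cross_attention`) can express the reduced variants.

## Training

KL divergence with ε-clipping (ε = 1e-7) is the loss; with one-hot targets
it equals weighted categorical cross-entropy (asserted to 1e-9). Class
weights enter once, as per-sample loss multipliers — not additionally as a
sampler — to avoid double-counting on top of WASW. Adam at 5e-4, batch 60,
160 epochs, ReduceLROnPlateau ×0.1 after 30 stale validation-loss epochs
with floor 1e-6, early stopping patience 50 (unpublished; configurable),
best-validation-accuracy weights checkpointed and restored. The learning
rate trace records the post-adjustment rate, so a plateau from epoch 1
shows the reduction at epoch 31.

## Metrics

All metrics are one-vs-rest from the confusion matrix, reported as
percentages with half-up rounding to two decimals. Per-class "accuracy" is
one-vs-rest accuracy (the only reading consistent with per-class values
exceeding the overall accuracy); the overall row is support-weighted for
Pre/Sen/Spe/F1 and plain multi-class accuracy for Acc. Zero-denominator
cells carry an explicit `None`. ROC-AUC and average precision use
scikit-learn; the test oracle is a brute-force pairwise-concordance count.

## Problem sizes used in the shipped tests

The end-to-end test trains on 40 records/class of 30 s (not the full
5-minute study condition), giving 2016 training windows after WASW, with
the reduced-width `tiny_config` (~71 k parameters, max-pool 25) for 12
epochs at batch 60 and lr 1e-3 — about five minutes on one CPU — and
evaluates 96 non-overlapping test windows. Generator *defaults* remain the
study conditions (250 Hz, 300 s, the class heart-rate ranges above); only
the test-scale record count, duration and model width are reduced. The
overfit-one-batch and unit tests use 2 s windows at reduced rates purely
for speed.

## Known limitations

* The numpy stack is single-threaded apart from BLAS matmuls; training the
  full-width model at realistic dataset sizes is out of scope (minutes per
  epoch).
* The generator's class separability means headline metrics here say
  nothing about real-world PPG difficulty (artifacts, AF-like
  irregularity, inter-subject variation).
* The WFDB reader is a thin optional path and is untested in CI (no
  network, optional dependency).
* BatchNorm running statistics use a fixed 0.9 momentum; very short
  training runs evaluate with partially burned-in statistics (mitigated by
  checkpoint selection on validation accuracy).
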