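# ppgrhythm

Four-class arrhythmia classification from single-channel photoplethysmography
(PPG), built as a fully testable pipeline: a synthetic rhythm generator, the
signal-conditioning chain, class-imbalance-aware window augmentation,
spectral self-similarity features, a dual-branch time/frequency attention
network, training, and a confusion-matrix metric suite.

## Who this is for

Researchers and engineers working on PPG-based rhythm monitoring (wearables,
bedside alarms) who need a reference implementation of a dual-domain
attention classifier that runs end-to-end on a laptop CPU without
downloading clinical waveform databases. The real-data path (WFDB records
with a PLETH channel) is supported but optional; every result in the test
suite is produced on synthetic data whose rhythm semantics follow the
standard critical-alarm definitions:

| class | definition |
|---|---|
| Bradycardia | heart rate below 40 bpm |
| Tachycardia | heart rate above 140 bpm |
| Ventricular tachycardia (VT) | ventricular beats at ≥ 100 bpm, distinct pulse morphology |
| Ventricular flutter/fibrillation (VF) | sustained oscillatory waveform, dominant energy in 4–7 Hz |

## The model

Each 10 s window (250 Hz) is classified by two branches fused with
attention:

* **Time branch** — causal conv stem + max-pool → two residual conv blocks
  (conv–BN–ReLU ×2 with shortcut) → cross-scale interactive attention, in
  which the deep residual features serve as query/key and a projected
  global-average-pooled reconstruction of the stem features serves as the
  value, Attention(Q,K,V) = softmax(QKᵀ/√d_k)·V with 4 heads and a residual
  LayerNorm wrapper Y = LN(MHA(Q,K,V) + X) → two BiLSTM layers.
* **Frequency branch** — Welch PSD per window,
  P_k(f) = |FFT(x_k·w)|²/U with U = (1/L)Σw², averaged over K segments;
  band energies are arctan-compressed into [0, π/2) and assembled into a
  self-similarity matrix S = X·Xᵀ whose rows are the token sequence for a
  Transformer-style encoder (sinusoidal positional encoding with a
  learnable depthwise-conv adjustment, 4-head self-attention, residual
  LayerNorm, FFN), then a 1×1 conv projection and a BiLSTM along the band
  axis.
* **Fusion head** — projection to a common width, linear upsampling +
  zero-padding to align lengths, squeeze-excite channel attention per
  branch, cross-attention (frequency as Q, time as K/V), self-attention
  over the fused space, a GRU-inspired sigmoid gate
  z⊙cross + (1−z)⊙self, and flatten → FC → FC(4) → softmax.

Training uses Adam (lr 5·10⁻⁴), KL-divergence loss with inverse-frequency
class weights, batch 60, ReduceLROnPlateau (×0.1 after 30 stale epochs),
early stopping, He-normal init, dropout 0.2. Class imbalance is also
addressed before training by weight-aware sliding-window augmentation: each
class slides its 10 s window with stride

    S_c = clip(round(S_ref / w_c^β), S_min, S_max),   S_ref=250, S_min=125, S_max=500, β=1

so rarer classes are sampled more densely. The default network configuration
has 1,541,796 trainable parameters (within 10 % of the 1.46 M design
budget). The whole network, including its training loop, runs on a compact
numpy autodiff stack shipped in `ppgrhythm.nn` (gradients are verified
against finite differences in the tests).

## Worked example

```python
from ppgrhythm import (SimParams, make_dataset, preprocess_record,
                       stratified_split, AugmentConfig, WelchConfig,
                       DualBranchAttentionNet, tiny_config, TrainConfig,
                       FeatureSet, fit, evaluate_predictions,
                       compute_class_weights)
from ppgrhythm.windowing import build_window_sets

records = make_dataset(40, SimParams(duration_s=30.0, seed=2025))
clean = [preprocess_record(r) for r in records]
sets = build_window_sets(clean, stratified_split(clean, seed=1),
                         AugmentConfig())
feats = {s: FeatureSet.from_window_set(ws, WelchConfig(n_bands=16))
         for s, ws in sets.items()}
counts = {int(c): int((feats["train"].y == c).sum()) for c in range(4)}
model = DualBranchAttentionNet(tiny_config(window_samples=2500), seed=3)
fit(model, feats["train"], feats["val"],
    TrainConfig(epochs=12, batch_size=60, lr=1e-3, seed=4),
    class_weights=compute_class_weights(counts), verbose=True)
probs = model.predict_proba(feats["test"].x_time, feats["test"].x_ssm)
report = evaluate_predictions(feats["test"].y, probs)
print(report.to_dataframe().to_string(index=False))
```

prints (after twelve ~16 s epochs; training accuracy reaches 0.98 by epoch
2 and validation accuracy 1.0):

```
  class   TP  FP   TN  FN   Pre   Sen   Spe    F1   Acc
  Brady 24.0 0.0 72.0 0.0 100.0 100.0 100.0 100.0 100.0
  Tachy 24.0 0.0 72.0 0.0 100.0 100.0 100.0 100.0 100.0
     VT 24.0 0.0 72.0 0.0 100.0 100.0 100.0 100.0 100.0
     VF 24.0 0.0 72.0 0.0 100.0 100.0 100.0 100.0 100.0
Overall  NaN NaN  NaN NaN 100.0 100.0 100.0 100.0 100.0
```

Per class: TP/FP/TN/FN are one-vs-rest counts over the 96 non-overlapping
test windows; Pre/Sen/Spe/F1/Acc are percentages (Acc per class is
one-vs-rest accuracy, the overall row is support-weighted with plain
multi-class accuracy). The four synthetic rhythms are fully separated at
this scale — the generator's classes differ in pulse rate, morphology and
spectrum by construction.

The same pipeline is available from a shell:

```bash
ppgrhythm run --config configs/tiny.yaml --out runs/demo --seed 0
```

## Layout

```
src/ppgrhythm/
  synth.py        synthetic rhythm generator + dataset container I/O
  preprocess.py   bandpass / smoothing / baseline correction / min-max
  windowing.py    stratified record-level split, WASW augmentation
  spectral.py     Welch PSD, arctan compression, self-similarity matrix
  attention.py    scaled dot-product + multi-head attention primitives
  nn/             numpy autodiff engine, layers, Adam
  model.py        time branch, frequency branch, fusion head, checkpoints
  train.py        KL loss, callbacks, seeded fit loop
  evaluate.py     confusion matrix, Pre/Sen/Spe/F1/Acc, ROC/PR
  pipeline.py     validated run config + stage orchestration
  cli.py          click CLI (simulate/preprocess/windows/train/evaluate/run)
docs/methods.md   modelling notes, defaults and their rationale
```
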