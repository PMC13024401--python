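# ecgrhythm

Rhythm triage for single-lead 10 s ECG strips — the kind recorded by
chest-patch and smartwatch monitors. The package classifies a strip into
one of five clinically graded categories:

| Label | Rhythm | Defining features |
|---|---|---|
| NSR | normal sinus rhythm | 60–100 bpm, full P-QRS-T |
| ST | sinus tachycardia | >100 bpm, sinus morphology |
| SB | sinus bradycardia | <60 bpm, sinus morphology |
| SVT | supraventricular tachycardia | rapid, narrow QRS, P obscured/absent |
| VT | ventricular tachycardia | rapid, wide (>120 ms) distorted QRS |

NSR/ST/SB share morphology and differ only in rate; ST/SVT/VT overlap in
rate and differ in morphology — so the classifier must read both.

## Method

A strip is standardized (resampled to 250 Hz, 2500 samples, z-scored over
the full 10 s interval) and cut into 1 s sliding windows with a 5-point
stride: floor((2500−250)/5)+1 = **451** windows per strip, turning 300
recordings per class into 135,300 training windows.

Each window is scored by a lightweight transformer. A learnable **Time2Vec**
embedding replaces fixed positional encoding:

```
t2v(τ)_i = ω_i τ + φ_i         i = 0        (linear trend)
t2v(τ)_i = sin(ω_i τ + φ_i)    1 ≤ i ≤ k    (periodic, k = 2)
```

Per time step, a projection of the scalar sample and a projection of the
3-dim Time2Vec column are summed element-wise into a d_model-wide sequence,
which passes through 3 post-norm encoder layers — multi-head scaled
dot-product self-attention, `softmax(QKᵀ/√d_k)V`, plus a position-wise ReLU
feed-forward network, each wrapped in `LayerNorm(x + Sublayer(x))` — then
mean pooling and a two-layer softmax head over the 5 classes.

The 451 window predictions are fused by **majority voting**,
`ŷ = argmax_c Σ_j 1[C_j = c]`, so sporadic noisy windows cannot flip the
recording-level call. Evaluation reports the 5×5 confusion matrix and
per-class Accuracy, Sensitivity, Specificity, Precision, F1 and
one-vs-rest AUC.

Everything (forward, backward, Adam) is implemented in NumPy; a
deterministic synthetic P-QRS-T generator supplies labeled five-class data
with patient-wise train/validation/test partitions, so the full pipeline
trains and evaluates with no downloads.

## Worked example

```python
import numpy as np
from ecgrhythm import (ModelConfig, NoiseConfig, RunConfig, SynthDatasetConfig,
                       TrainConfig, evaluate, generate_dataset, train)

cfg = RunConfig(
    model=ModelConfig.scaled_down(),          # d_model 64, 2 layers, 4 heads
    data=SynthDatasetConfig(per_class_count=40, seed=11, noise=NoiseConfig.clean()),
    train=TrainConfig(seed=0, stride=25, val_stride=100, windows_per_record=16,
                      batch_size=32, max_epochs=8, patience=3),
    split=(24, 8, 8),
    output_dir="run0",
)
model, hist = train(cfg, verbose=True)
ds = generate_dataset(cfg.data, split=cfg.split)
report, cm, _ = evaluate(model, ds.partitions["test"], S=25)
print(report.overall_accuracy)
print(cm.counts)
```

Output from this exact run:

```
epoch 0: train 1.3307 val 0.8163 rec-acc 0.650
epoch 1: train 0.6324 val 0.2737 rec-acc 0.950
...
epoch 7: train 0.1723 val 0.0725 rec-acc 1.000
100.0
[[8 0 0 0 0]
 [0 8 0 0 0]
 [0 0 8 0 0]
 [0 0 0 8 0]
 [0 0 0 0 8]]
```

i.e. training converges within a few epochs and every held-out recording
(8 per class, subjects disjoint from training) is voted into its true
rhythm class — 100% recording-level accuracy on this clean synthetic split.

A CLI wraps the same pipeline: `ecgrhythm generate`, `ecgrhythm train
--config run.yaml`, `ecgrhythm predict --checkpoint C --record strip.csv`,
`ecgrhythm evaluate --checkpoint C --manifest manifest.tsv`.

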