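# Methods

## Problem and model

The package classifies 10 s single-lead ECG strips into five rhythm
classes (NSR, ST, SB, SVT, VT). The design premise is that a 1 s window is
long enough to capture local morphology (P presence, QRS width) and short
enough that a dense sliding decomposition of the strip yields hundreds of
correlated-but-distinct training samples; rate information is recovered
partly within windows (inter-beat landmarks) and partly by the vote over
451 windows spanning the strip.

Pipeline: standardize → window → classify per window → majority vote.

* **Standardization.** Resample to 250 Hz (polyphase FIR for rational rate
  ratios, linear interpolation otherwise), enforce 2500 samples, z-score
  with the *population* standard deviation over the full 10 s interval.
  Full-interval scaling preserves relative morphology (R vs T height)
  across windows; the population/sample σ distinction is immaterial at
  n = 2500 but the population convention is fixed and tested. A constant
  strip raises a degenerate-signal error rather than returning NaNs.
* **Windowing.** W = 250 samples, stride S = 5; count = floor((L−W)/S)+1.
  When (L−W) is not divisible by S the trailing partial window is dropped,
  consistent with the floor. Windows are 0-based, half-open, and inherit
  the recording's label — the only consistent choice when training a
  window-level classifier whose targets exist per recording.
* **Window classifier.** Time2Vec embedding (k = 2: one linear + two sine
  rows, frequencies and phases learnable, τ = sample index 0…249 restarting
  per window) is fused with the signal by projecting, per time step, the
  scalar sample and the 3-dim Time2Vec column to d_model and summing
  element-wise. The encoder is post-norm: LayerNorm(x + Dropout(MHA(x))),
  then LayerNorm(x + Dropout(FFN(x))); the FFN is two kernel-size-1
  convolutions (position-wise linear→ReLU→linear, inner width ffn_dim).
  Mean pooling over the 250 positions feeds a linear→ReLU→dropout→linear
  head and softmax over 5 classes. Dropout is applied to sublayer outputs
  and between the head linears, not to attention weights.
* **Voting.** Hard argmax votes per window; ties break by higher mean
  softmax probability among tied classes, then fixed class order
  (NSR, ST, SB, SVT, VT). Recording-level scores for ROC/AUC are the mean
  window softmax vectors (a config-level choice; vote fractions would
  discard confidence).

### Head and width choices

The full-size configuration is d_model 256, 3 layers, 12 heads, ffn 1024,
dropout 0.25, L2 1e-3. Since 256 is not divisible by 12 heads, the
per-head width `key_dim` is an independent hyperparameter (default 21;
12×21 = 252 concatenated and projected back to 256 by W₀) — standard
multi-head attention imposes no h·d_k = d_model constraint. Pooling
(mean), head hidden width (64) and the training recipe (Adam, lr 1e-3,
batch 256 windows, cross-entropy on window labels, early stopping on
window-level validation loss, L2 as weight decay on weight matrices) are
package choices where the architecture leaves them open. The model card
always records the exact trainable-parameter count (2,375,015 at the full
defaults; 69,515 for the reduced configuration below).

### Numerical implementation

The network is pure NumPy with hand-written backpropagation (verified
against central finite differences at 1e-5) and an Adam optimizer.
float32 is the working precision for training; float64 is available for
exact numeric tests. Softmax is computed shift-stably; the attention
softmax and its Jacobian-vector product run in place on a 2-D view of the
(batch, heads, T, T) score tensor, which is the throughput-critical path
on CPU. Inference batches of ~32 windows are fastest cache-wise.

## Synthetic data generator

Each recording is a sum of Gaussian deflections per cardiac phase placed
on an R-R grid — deliberately parametric rather than a dynamical-system
model, because what the classifier must separate is rate and gross
morphology, not subtle ECG microstructure.

Class parameters (heart-rate ranges follow standard clinical conventions;
all configurable):

| Class | HR (bpm) | P wave | QRS | R-R jitter |
|---|---|---|---|---|
| NSR | 60–100 | present | narrow, 80 ms | 3% |
| ST | 100–150 | present | narrow, 80 ms | 2% |
| SB | 40–59 | present | narrow, 80 ms | 3% |
| SVT | 150–220 | absent (amplitude 0) | narrow, 80 ms | 1% |
| VT | 120–250 | absent | wide distorted, 160 ms | 4% |

Details: the heart rate of a recording is drawn uniformly from the central
90% of its class band (so the mean instantaneous rate stays inside the
band despite jitter); P and T offsets compress with rate (clipped scale
RR/0.8) as diastole shortens; the wide QRS is a broad R lobe plus a
trailing opposite lobe and discordant T, giving a measured half-height
width above 120 ms; R amplitude is normalized to 1.0 before noise, and
arbitrary amplitude units are removed downstream by z-scoring. Noise
defaults: baseline wander 0.15 relative amplitude at 0.3 Hz, white noise
σ 0.05, motion-artifact probability 0.05 (a Gaussian-windowed noise
burst); `NoiseConfig.clean()` switches all off for oracle-based tests.
Generation is a pure function of (label, dataset config, record seed).

Each synthetic subject owns exactly one recording (mirroring databases
where every 10 s strip comes from a distinct individual), so the
patient-wise partition is trivially leak-free; per-class counts are exact
and splits may be given as fractions or per-class counts.

**What the generator does not emulate:** real P/QRS/T shape variability
across individuals, atrial fibrillation and rhythms outside the five
classes, conduction abnormalities, electrode-motion artifact structure,
pediatric ranges, and the label noise of curated clinical data. Passing
tests on this data demonstrates that the pipeline learns rate+morphology
distinctions end to end and that its plumbing is correct — not clinical
performance on real recordings.

## Scaled-down end-to-end experiment

The CPU-scale experiment trains the reduced model — d_model 64, 2 layers,
4 heads (key_dim 16), ffn 128, dropout 0.1 — on clean synthetic data, 40
recordings per class split 24/8/8 per class subject-wise, windows at
stride 25 (91 per recording). The recipe subsamples 16 windows per
recording per epoch (adjacent 5-point windows are near-duplicates, so
dense windowing adds little per epoch), batch 32, lr 1e-3, up to 6 epochs
with patience 2 on validation loss; validation uses stride-100 windows,
with loss and the recording-level vote computed from one shared forward
pass. Held-out recording-level accuracy is evaluated at stride 25. These
problem sizes are the package's chosen desk-scale experiment; the
full-size configuration and dense stride-5 windowing remain available
through the same interfaces.

## Known limitations

* The minimal WFDB reader/writer covers single-segment records with one
  interleaved int16/int32 signal file — enough for fixtures and typical
  single/dual-channel strips, not the full format zoo; annotation files
  are not parsed. WFDB stores integer ADC counts, so write→read
  round-trips are exact only to the adaptive gain (~1e-9 relative at
  format 32); CSV round-trips are exact.
* Records shorter than 10 s are rejected; longer records require the
  explicit crop-first-10 s opt-in.
* Undefined metrics (zero denominators) propagate as NaN with a flag;
  downstream aggregation must handle them rather than assume 0.
* Training throughput is CPU-bound NumPy; the full-size model on dense
  stride-5 windows is best run on a machine with a fast BLAS and patience.
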