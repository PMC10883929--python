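# ecgfusion

Hybrid ResNet–ViT localization of myocardial infarction (MI) from
12-lead ECG. The package is aimed at researchers who want a fully
inspectable, dependency-light reference implementation of the
signal-to-diagnosis pipeline: wavelet denoising, Pan–Tompkins beat
segmentation, a multibranch squeeze-and-excitation (SE) convolutional
patch-embedding stem feeding a reduced-depth transformer encoder, a
residual-network feature branch, concatenation fusion, and a stratified
k-fold evaluation harness. Every stage is testable without clinical
data through a synthetic class-conditional ECG generator with known
R-peak ground truth.

## The method

**Pre-processing.** Each lead is denoised with a Daubechies-6 discrete
wavelet transform, X(a, b) = Σₙ s(n) ψ₍a,b₎(n), soft-thresholding detail
coefficients at the universal threshold σ√(2 ln N). R peaks are found
by the Pan–Tompkins cascade (bandpass 5–15 Hz → derivative → squaring →
moving-window integration → adaptive dual thresholds with searchback),
and each beat is cut to 651 samples: 250 before the R peak, 400 after.
The integration window W trades missed against spurious detections
through a cost C(W) = miss + false + λ·T-wave-overlap, minimized over a
candidate grid; the chosen window relates to the sampling rate as
W = k / fs.

**Two feature branches.** A residual network (basic blocks
Hᵢ = Hᵢ₋₁ + F(Hᵢ₋₁); 3×3 stride-1 stem, 3×3 stride-2 max-pool, 64
initial filters) with its classifier removed emits the global-average-
pool vector F_ResNet. In parallel, the "slim" stem replaces the usual
16×16 patch-embedding convolution: four stage modules, each computing
O(x) = F_{s=2}(x) + L_{s=2}(x) then SE[F_{s=1}(O) + L_{s=1}(O) + O],
take a 224×224 image through 112/56/28/14 with 48/96/192/384 channels,
and a 1×1 convolution expands to 768 — a 14×14×768 embedding map. A
pre-norm transformer encoder two layers shallower than its ViT-Base
reference (depth 10) processes the 196 patch tokens plus a class token;
the last hidden states (class token excluded) are flattened and mapped
by one dense layer, F = W_f·Flatten(H) + b_f, to the ResNet feature
length.

**Fusion and evaluation.** The two equal-length vectors are
concatenated and classified through a dense head with softmax over the
12 classes (healthy control + 11 MI localizations). Evaluation uses
stratified 10-fold cross-validation with per-class one-vs-rest
accuracy, precision, recall/sensitivity, specificity, F1, FPR, FNR,
confusion matrices (counts and row-percent) and one-vs-rest ROC/AUC.

All networks are implemented as a small NumPy layer library with manual
backprop (`ecgfusion.nn`) — no deep-learning framework required.

## Worked example

```python
import numpy as np
from ecgfusion.synthetic import generate_record, make_dataset
from ecgfusion.preprocess import preprocess_record
from ecgfusion.fusion import (TrainConfig, build_hybrid_model,
                              kfold_evaluate, reduced_model_config)

# 10 noiseless inferior-MI beats with known R-peak ground truth
sr = generate_record("Inferior", n_beats=10, fs=360, noise_snr_db=None, seed=3)
beats = preprocess_record(sr.record, label="Inferior")
print(len(beats), beats[0].values.shape)          # 10 (651, 12)

# end-to-end: 12 classes x 20 rendered beats, reduced-width hybrid model
_, ds = make_dataset(n_per_class=20, noise_snr_db=20, seed=5, image_size=48)
builder = lambda s: build_hybrid_model(reduced_model_config(48), seed=s)
reports, table = kfold_evaluate(ds, builder, TrainConfig(epochs=25), k=10, seed=0)
print(round(np.mean([r.accuracy for r in reports]), 3))   # 0.971
```

The first block prints `10 (651, 12)`: all ten generated beats survive
denoising, detection and segmentation, each a 651-sample, 12-lead
window. The second prints the 10-fold mean accuracy on the synthetic
benchmark (`0.971` with these seeds): with the configured ±0.2 mV ST
offsets and pathological Q waves, the reduced hybrid model separates
the twelve localization classes almost perfectly.

A `ecgfusion` console command exposes the same pipeline
(`preprocess`, `synth`, `train`, `evaluate`); see `ecgfusion --help`.

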