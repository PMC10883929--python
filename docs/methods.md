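# Methods

This note records the scientific and numerical choices behind
`ecgfusion`, in the spirit of a model-description appendix: what is
computed, under which assumptions, and where the design was genuinely
open.

## Signal model and pre-processing

ECG records are real matrices (samples × leads) in millivolts with a
known sampling rate; the conventional 12-lead order (I, II, III, aVR,
aVL, aVF, V1–V6) is fixed throughout. Records whose sampling rate
differs from the configured target are polyphase-resampled first so
that fixed sample offsets keep their physical duration.

**Wavelet denoising.** Each lead is decomposed with a Daubechies-6
wavelet to level min(4, maximum level permitted by the signal length) —
the standard choice for ECG, deep enough to reach baseline-wander
scales at a few hundred hertz without over-smoothing the QRS. Detail
coefficients are soft-thresholded at the universal threshold
σ√(2 ln N) with σ estimated from the median absolute deviation of the
finest detail level (MAD/0.6745). Soft thresholding is the default
because it avoids the spurious spikes hard thresholding can leave next
to the QRS. Setting the threshold scale to zero makes the transform a
perfect-reconstruction identity, which the tests exploit.

**R-peak detection.** The classic five-stage cascade with its canonical
constants, all exposed in `PeakDetectorConfig`: Butterworth bandpass
5–15 Hz (order 2, zero-phase), derivative, squaring, moving-window
integration over 150 ms, adaptive dual thresholds (signal/noise running
estimates updated with factor 0.125, detection threshold at
noise + 0.25·(signal − noise), the second threshold at half the first),
a 200 ms refractory period, T-wave discrimination by slope within
360 ms of the previous QRS, and searchback at 1.66× the running RR
average. Integrator peaks are finally snapped to the raw-signal maximum
within ±75 ms plus half the integration window, since the integrator
output lags the QRS. Detection runs on one configurable lead (default
II — the customary rhythm lead); segmentation then slices all leads at
the detected indices.

**Segmentation.** Beats are windows of left + right + 1 samples around
each R peak, 250/400 by default (651 samples). Peaks too close to a
record edge are dropped by default; an edge-padding policy is available
but not used in the evaluation pipeline, because padded beats would
distort the rendered morphology.

**Integration-window selection.** The window cost is instantiated as
C(W) = miss_rate + false_rate + λ·twave_overlap, where twave_overlap is
the fraction of detections closer to an annotated T-wave apex than to
the true R peak. `optimize_window` evaluates a candidate grid on
annotated records and returns the argmin, ties broken toward the
smaller window (smaller windows react faster and are preferred when
nothing distinguishes the candidates); the report includes
k = W_optimal × fs so the choice transfers across sampling rates by
W = k / fs.

## Architecture

**Slim stem.** Four stage modules, each: O(x) = F_{s=2}(x) + L_{s=2}(x)
(3×3 and 1×1 stride-2 branches, both carrying the width change so the
later identity addition is width-consistent), then
H(x) = SE[F_{s=1}(O) + L_{s=1}(O) + O]. Every convolution is followed
by batch normalization (momentum 0.1, epsilon 1e-5) and ReLU, in that
order. The SE module is global average pool → dense (C → C/r) → ReLU →
dense (C/r → C) → sigmoid gates, r = 16 by default with a floor of one
hidden unit. After the stages a 1×1 convolution expands 384 → 768
channels. Odd spatial sizes are rejected rather than padded so the
224 → 112 → 56 → 28 → 14 contract stays exact.

**Transformer branch.** The 14×14×768 map is flattened row-major into
196 tokens, a learned classification token is prepended and learned
positional embeddings (length 197) are added. Encoder blocks are
pre-norm multi-head self-attention + GELU MLP — the de-facto ViT
standard — with ViT-Base reference hyperparameters (12 layers, 12
heads, MLP ratio 4); the built encoder always has two layers fewer
than its reference depth (10 by default). No final layer norm is
applied after the last block: the feature head consumes the last
attention layer's hidden states directly, classification token
excluded, flattened and mapped by a single dense layer to the residual
branch's feature length.

**Residual branch.** The stem is a 3×3 stride-1 convolution into 64
filters followed by a 3×3 stride-2 max-pool (rather than the canonical
7×7 stride-2 stem). The default body is the 18-layer basic-block
layout ([2,2,2,2], feature length 512); a 50-layer bottleneck variant
([3,4,6,3], length 2048) is selectable. The network ends at the global
average pool — head removal is structural, there is no masked
classifier. Weights initialize randomly (He); externally supplied
checkpoints can be loaded onto the `Param` values but none ship with
the package.

**Fusion.** The two equal-length feature vectors are concatenated
(parity is asserted at construction) and passed through one hidden
dense layer (256 units, ReLU, dropout 0.35 at full scale) and a softmax
output over 12 classes. Both branches and the head train jointly by
default; `freeze_resnet` supports the staged reading in which only the
transformer branch and head adapt.

## Training and evaluation

Adam at learning rate 0.001 (the documented rate; Adam is this
package's choice of optimizer), categorical cross-entropy, batch 32.
All randomness — initialization, batch shuffling, dropout — derives
from explicit seeds, so runs are bit-reproducible on the same
platform. Evaluation is stratified 10-fold cross-validation with the
model re-initialized per fold. Per-class "accuracy" is one-vs-rest
(TP+TN)/N; aggregate precision/recall/F1 are macro averages; ROC curves
are one-vs-rest threshold sweeps. The identities FNR = 1 − sensitivity
and FPR = 1 − specificity hold exactly by construction and are asserted
to 1e-9 in tests.

## Synthetic data: what it emulates and what it does not

Beats are sums of Gaussian bumps (P, Q, R, S, T) with per-lead
projection factors, repeated at 75 bpm with 2% RR jitter at 360 Hz
(configurable; 360 Hz makes the 250/400-sample offsets span
0.69/1.11 s). Class signatures modify leads the way clinical ECG
reading expects: a smooth ST-segment plateau of ±0.2 mV on the leads
facing (or reciprocal to) the infarct, pathological Q waves at 40% of
the lead's R amplitude and 60 ms width, and T-wave inversion where
appropriate. Six of the twelve signatures follow the documented sample
descriptions (healthy control; anterior; anterolateral; anteroseptal;
anteroseptal-lateral; inferior with its reciprocal depressions); the
remaining five MI localizations use standard clinical lead patterns
chosen once. The twelve ST-offset patterns are pairwise distinct, so
the classes are separable from ST-window means alone — this is what
makes the end-to-end classification property attainable by
construction. White Gaussian noise is added at a configured SNR
(default 20 dB for dataset assembly); the noiseless reference and true
R-peak indices are stored with every record.

Beat images are rendered by a deterministic polyline rasterizer: white
background, dark anti-aliased trace, a fixed symmetric ±1.3 mV span per
lane so 0 mV sits at the lane center, leads stacked in canonical order
(a 4×3 grid layout is available). Determinism is part of the renderer's
contract — identical beats produce identical pixels on any platform.

What the generator does **not** emulate: realistic ECG dynamics
(no dynamical-system model), rhythm disorders, baseline wander, muscle
or electrode artifacts, inter-patient morphology variation, or the
class-imbalance and label noise of clinical datasets. Passing the
synthetic benchmarks therefore demonstrates that the pipeline and
architecture are implemented correctly and can learn lead-localized
ST/Q signatures end-to-end; it says nothing about accuracy on real
clinical ECG.

## Problem sizes used in the shipped benchmarks

The package's own evaluation runs at desk scale by design: the
synthetic benchmark uses 12 classes × 20 beats rendered at 48×48
pixels, and a reduced-width model with the identical topology — slim
stage widths [8, 12, 16, 24] into 48 embedding channels, a
reference-4 (depth-2) encoder with 4 heads, an 8-filter [1,1,1,1]
residual branch (feature length 64), and a 48-unit fusion hidden layer
(~192k parameters). Training runs 25–30 epochs. The full-scale
configuration (224×224, 48/96/192/384→768 stem, depth-10 encoder,
512-length residual features) is exercised shape-exactly in tests and
by `scripts/acceptance.py`, but not trained in the shipped benchmarks.

## Numerical notes and limitations

* All tensors are float64; convolutions run as im2col + GEMM, and every
  layer's backward pass is verified against central finite differences
  in the test suite.
* Batch-norm uses batch statistics in training and running estimates in
  evaluation; with a frozen residual branch its running statistics
  still update during training passes.
* Softmax rows are computed with max-subtraction; attention rows sum to
  one within 1e-6 by test.
* Argmax ties break toward the lower class index (NumPy argmax
  convention).
* Degenerate inputs: a flat signal yields no detected peaks (not an
  error); an empty peak list yields an empty segment list; an
  all-constant beat renders a straight line.
* The WFDB reader supports format-16 header/.dat pairs only — enough
  for interchange with the common open ECG archives, not a full format
  implementation.
* Training the full-scale model is computationally impractical in pure
  NumPy; the reduced configuration exists precisely so that every
  claim shipped with the package is recomputed, not quoted.
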