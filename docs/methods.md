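# Methods

This note documents the models and procedures implemented in
`coughscope`, the parameter choices that matter, and what the synthetic
benchmark does and does not demonstrate.

## Signal front end

Recordings are handled as mono float waveforms. The working sample rate
defaults to 16 kHz — cough energy is concentrated well below the 8 kHz
Nyquist bound, and 16 kHz keeps FFT sizes standard; any other input
rate is polyphase-resampled at load time. Amplitude normalization is
peak normalization to [−1, 1] (the simplest testable contract; the
original recording protocol relied on manual editing and does not pin
down a scheme). An optional energy trimmer (drop leading/trailing 25 ms
frames whose RMS falls below 1% of the peak frame RMS) stands in for
manual endpoint editing; it is off by default because silence at clip
edges is harmless to the spectrogram features.

Segmentation is deterministic: consecutive non-overlapping 3-second
windows; a trailing remainder of at least 0.5 s is zero-padded to full
length, shorter remainders are dropped (avoids near-empty padded
segments); inputs shorter than one window yield exactly one zero-padded
segment. Pre-emphasis is `y[n] = x[n] − μ·x[n−1]` with μ = 0.97, the
conventional speech value; μ outside [0.9, 1] is rejected unless
explicitly overridden. The filter is exactly invertible
(`x[n] = y[n] + μ·x[n−1]`), which the tests exploit as a round-trip
property.

## Spectrogram features

25 ms frames with a 10 ms hop (400/160 samples at 16 kHz) balance
temporal and spectral resolution for short transient sounds. Each frame
is multiplied by a Hamming window of its own length, zero-padded to 512
points, and transformed; only complete frames are taken
(`n_frames = floor((N − L)/H) + 1`, 298 frames for a 3 s segment), so a
spectrogram is 257 × 298. Magnitudes become dB via
`20·log10(|X| + ε)` with ε = 1e−10, keeping the image finite for silent
frames. For the network the dB image is min–max normalized per image
(removes recording-gain differences) and bilinearly resized to a square
input (224 default; the scaled-down experiments use 64). PNG export
maps dB linearly to 8-bit gray with darker = higher amplitude and low
frequencies at the bottom.

## Network

The classifier is an 18-layer residual network with a channel attention
gate in every basic block. Stem: 7×7 convolution, stride 2, padding 3,
64 channels; 3×3/stride-2/padding-1 max pooling; four stages of two
basic blocks with 64/128/256/512 channels, the first block of stages
2–4 downsampling with a stride-2 1×1 projection skip; global average
pooling; a fully connected layer to 5 classes. Blocks are
conv–BN–ReLU–conv–BN. The attention weights are computed from the block
output `F(x)` after the second batch norm: spatial global max- and
average-pooling produce two C-vectors; a *shared* MLP maps each to C
scores; `M_c = σ(MLP(avg) + MLP(max))`. The gate is applied **after**
the skip addition, `Z = M_c · (F(x) + x)`, followed by the usual ReLU.
A `pre_sum` option applies the more common `Z = M_c · F(x) + x`
placement for comparison. With attention disabled the build is exactly
the plain 18-layer network (11,172,805 parameters at 1 input channel
and 5 classes), and forcing all gates to one reproduces it bit-for-bit
— the ablation tests rely on this identity.

The shared MLP is three affine maps C → 256 → ReLU → 128 → ReLU → C.
The two hidden widths are the stated sizes of the attention
perceptron's fully connected layers; because an output projection back
to C is also required to produce per-channel weights, the literal
reading yields three affine maps rather than two, and the hidden sizes
stay configurable. Spectrogram input is single-channel, so the stem
accepts 1 channel (`input_channels` is a knob); batch normalization is
intrinsic to the backbone and on by default with a disable flag.

Initialization is He (fan-out with ReLU gain for convolutions, fan-in
for linear layers; BN scale 1, shift 0), seeded — identical seeds give
bit-identical builds.

### NumPy engine

The network, backpropagation, Adam and the LR schedule live in
`coughscope.nn`: convolution is im2col plus BLAS matmul with the
standard col2im accumulation for input gradients; max pooling uses −∞
padding so padded positions never win. All gradients are verified
against central finite differences in the test suite. Inference-mode
batch-norm statistics are re-estimated after every epoch with a
"precise BN" pass (averaging batch statistics over up to 16 training
batches under the frozen current weights) because short training runs
move the weights far faster than an EMA can track; without this,
validation accuracy lags training accuracy badly at desk scales.

## Training and evaluation protocol

Stratified k-fold cross-validation (k = 5 by default; fold sizes differ
by at most one, class proportions preserved within one sample per
fold). Per fold: Adam (lr 0.001, β = (0.9, 0.999), ε = 1e−8 — the
library-standard constants), batch size 8, 50 epochs, step decay
`lr(e) = 0.001 · 0.1^floor(e/7)` stepped per epoch, cross-entropy loss.
After every epoch validation accuracy is measured; the weights with the
highest validation accuracy are checkpointed (ties → earliest epoch).
"Best weights" is read as best *validation* accuracy — the standard
interpretation — and both loss and accuracy curves are recorded.
Checkpoints are single NPZ archives holding weights, BN statistics, the
network config and metadata, so reloading reproduces the recorded
accuracy exactly.

Metrics are one-vs-rest per class: precision, recall (= sensitivity),
specificity, F1; overall accuracy is the trace of the confusion matrix
over the total. Undefined 0/0 ratios are reported as 0 and flagged, so
macro averages never propagate NaN. Across folds the report gives the
mean, sample SD (n−1), and a 95% CI as mean ± 1.96·SD/√k; a Student-t
variant (k−1 df) is emitted alongside since the normal approximation is
optimistic at k = 5. Multi-class specificity/sensitivity are macro
averages of the one-vs-rest values.

Noise robustness corrupts the *waveforms* of the evaluation split with
additive white Gaussian noise scaled to a requested SNR (30/20/10 dB
rows plus a noiseless row), re-extracts spectrograms, and re-evaluates.
The noise variance is set from the measured signal power, so the
realized SNR is within a fraction of a dB at 3 s × 16 kHz. White
Gaussian noise is the default because no specific interference type is
singled out; the harness accepts alternative noise sources.

## Synthetic corpus

Each synthetic cough is a train of 2–4 noise bursts: white noise
through second-order resonators at class-specific center frequencies,
under a fast-attack/exponential-decay envelope (decay 0.09–0.18 s),
over a −30 dB broadband floor, peak-normalized, exactly 3 s. The five
default classes differ by at least 300 Hz in at least one resonance,
which makes them separable by construction — a linear model on
time-averaged log-spectra exceeds 90% held-out accuracy. Default size
is 2610 clips, 522 per class (even split; the printed per-class
training-set sizes in the source material are internally inconsistent,
so the even split is the default and a `table1` preset provides the
420/435/413/398/425 training-set shape, total 2091). Per-sample seeds
are derived from the master seed by hashing, so any single file can be
regenerated in isolation.

A `hard` preset narrows the inter-class resonance gaps to 150 Hz
spacing with wide overlapping bandwidths so accuracy does not saturate;
it is the preset used for attention-on vs attention-off comparisons,
whose difference is *reported, not asserted* — at desk scale the sign
of the gap is seed-dependent.

What passing tests show: the pipeline is wired correctly end to end —
features carry class information, the network can extract it, the
protocol accounts for every sample exactly once, and the noise harness
corrupts at calibrated SNR. What they do not show: anything about
clinical cough recordings. The generator does not model airway
physiology, dry/wet cough distinctions, recording-device variation, or
demographic covariates, and its class separations are chosen, not
measured.

## Problem sizes and numerical choices

The scaled-down protocol used by the acceptance script and the
heaviest tests is 100 samples/class, 64×64 inputs, 2 folds, 5 epochs —
chosen as the smallest configuration at which the network reliably
reaches high validation accuracy on the default corpus. The network
runs in float32; spectrogram math in float64. Degenerate inputs are
handled explicitly: all-zero segments produce constant dB images that
map to all-zero model inputs; all-zero signals pass through peak
normalization unchanged; SNR is undefined (rejected) for silent
segments. Prediction ties break toward the lowest class index.

## Known limitations

- No real-data validation of any kind; the synthetic benchmark is a
  plumbing test, not a clinical result.
- The NumPy engine is single-threaded except for BLAS matmuls; large
  (224×224, 50-epoch, 5-fold) runs are possible but slow — hours, not
  minutes, on one core.
- No cough/non-cough detection, denoising, or out-of-set ("other
  cough") rejection.
- The attention gate's placement after the skip sum follows the
  composite formula literally; most channel-attention literature gates
  before the sum. Both are implemented; only the post-sum form is the
  default.
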