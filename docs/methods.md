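# Methods

## The reconstruction model

The network is a convolutional autoencoder `x~ = f(g(x))`: the encoder `g`
compresses a scattered NIR surface capture into a latent feature stack, and
the decoder `f` reconstructs the hidden pattern. The architecture is a
U-Net whose skip connections **add** the encoder feature map of each
resolution to the decoder activation at the same resolution (instead of
concatenating channels). Additive skips force the decoder's channel plan to
mirror the encoder's exactly; `build_unet` verifies this structurally, so a
mis-registered variant fails at construction rather than at training time.

Layout per registered variant:

| variant    | encoder channels        | bottleneck | blocks |
|------------|-------------------------|------------|--------|
| `main768`  | 64, 128, 256, 512, 768  | 768        | 5      |
| `big1024`  | 64, 128, 256, 512, 768  | 1024       | 5      |
| `small512` | 128, 256                | 512        | 2      |
| `tiny96`   | 16, 32, 48, 64, 96      | 96         | 5      |

Each encoder block is (3×3 conv → batch norm → ReLU) × 2 followed by 2×2
max-pooling; the bottleneck is two further convolutions at the bottleneck
width; each decoder stage is 2× bilinear upsampling → channel-matching
conv → batch norm → **+ skip** → ReLU → conv → batch norm → ReLU; the head
is a 3×3 conv to one channel with sigmoid, so outputs lie in (0, 1). The
intermediate channel plan 64→768 doubles until the stated maximum; the
two-block variant reads the "two layers" description as two encoder blocks
with channels (128, 256) feeding a 512-channel bottleneck, preserving the
doubling pattern. `tiny96` scales `main768`'s plan down proportionally for
CPU-size benchmarks.

Design choices where the architecture description left latitude:

* **Block order** conv → batch-norm → ReLU (normalization before
  activation, the common convention).
* **Upsampling** bilinear interpolation followed by a 3×3 convolution
  (avoids checkerboard artifacts); nearest-neighbour is available through
  `UNetConfig.upsample_mode`.
* **Non-divisible sizes.** 200 is not divisible by 2⁵; inputs are
  symmetrically zero-padded to the next multiple of 2^depth inside
  `forward` and the output is center-cropped back, keeping the I/O
  contract at the nominal size.
* **Initialization** He-uniform, fully seeded; the sigmoid head's bias
  starts at logit(0.1) — the glyphs' typical foreground fraction — so the
  network does not spend its first epochs relearning that targets are
  mostly dark (the standard imbalance-aware output init).
  **Checkpointing** keeps the epoch with the best validation MSE.
* **Inference determinism.** Batch norm uses running statistics in
  evaluation mode, so evaluation outputs are bit-reproducible and
  batch-size independent.

## The NumPy network engine

The layers (`nirunet.nn`) are implemented directly in NumPy with explicit
backward passes. Activations are stored channel-major `(C, N, H, W)` so a
stride-1 same-convolution over the whole batch is a single wide GEMM
against a column matrix assembled by nine contiguous tap-slice copies; the
input gradient is itself a convolution (flipped, channel-transposed
kernel) on the same fast path, and the weight gradient is one GEMM against
the column matrix. Large short-lived buffers (columns, padded inputs) come
from a reusable scratch arena — repeated fresh allocation of
hundred-megabyte buffers costs more in page faults than the arithmetic.
Gradients of every layer are verified against float64 central differences
in the test suite. The engine is single-threaded by design and treats
float32 as the working precision.

## Training

Adam (β₁ = 0.9, β₂ = 0.999), MSE loss — literally the same function the
metrics module exports, so the trainer's loss and the reported MSE cannot
drift apart — batch size 25, learning rate 10⁻³. All randomness
(initialization, shuffling) derives from `TrainConfig.seed`; identical
configurations reproduce identical loss histories bit for bit. A non-finite
loss aborts with the offending epoch. `train_arrays` accepts an optional
wall-clock budget: after each epoch it stops early if another epoch would
not fit. This keeps fixed-runtime harnesses honest — the checkpoint records
how many epochs actually ran — and changes nothing when the budget is
ample.

## The forward simulation

The generator emulates a transmission rig: a high-contrast pattern beneath
~5 mm of scattering tissue, imaged at 780 nm under oblique halogen
illumination. Each physical effect maps to one parameter
(`PhantomParams`), and each stage can be switched off independently:

1. absorption contrast: `r = background_level · (1 − attenuation·target)`,
   with `background_level = 0.65`, `attenuation = 0.55` — captures are
   *darker* where the pattern lies;
2. multiplicative planar glare ramp (amplitude 0.25 at 45°, zero-mean);
3. isotropic Gaussian PSF with σ = 1.6 px/mm × thickness (reflective
   boundaries) — 8 px at the 5 mm default, a severe low-pass;
4. multiplicative speckle, std 0.08;
5. additive sensor noise, std 0.02;
6. clip to [0, 1], quantize to 8 bits.

Targets are generated glyphs (seven-segment digits, rectangles, rings,
random polylines) with foreground fractions kept in [0.03, 0.45]; an IDX
reader makes MNIST-format archives usable as an alternative target source
without any download at build time. The blur/attenuation/noise levels were
chosen once so that raw captures score a few dB PSNR and near-zero SSIM
against their targets — the regime the physical study reports — and are
not tuned thereafter.

What the simulation does **not** model: radiative transfer or photon-path
physics, wavelength dependence, camera geometry or registration error,
spatially varying tissue thickness, and the heavy-tailed artifacts of real
specimens. Passing the synthetic benchmark therefore demonstrates that the
architecture and training recipe can invert this class of degradation; it
does not certify performance on physical captures.

## Metrics

* **MSE / PSNR** exactly by their closed forms; zero-MSE pairs report an
  infinite-PSNR sentinel and are excluded (with a logged count) from PSNR
  averages rather than capped.
* **SSIM** via scikit-image with the original publication's constants
  (11×11 Gaussian window, σ = 1.5, K₁ = 0.01, K₂ = 0.03, population
  covariances); the test suite pins it to within 10⁻⁶ of an independent
  valid-region implementation of the published formula.
* **FSIM** implemented in `nirunet.fsim` as a port of the published
  algorithm: phase congruency from a 4-scale × 4-orientation log-Gabor
  bank (minimum wavelength 6, multiplier 2, σ_onf 0.55, Butterworth
  low-pass 0.45/15) with Rayleigh noise-floor compensation, Scharr 3×3
  gradients, T₁ = 0.85, and T₂ = 160 on a 0–255 scale — inputs in [0, 1]
  are rescaled by 255 internally so the published constants keep their
  meaning. Filter banks are cached per image size. No independent FSIM
  package exists in this environment, so the suite cross-checks against a
  separate literal transcription of the published procedure.
* **Failure counting** defines a failed reconstruction as SSIM < 0.5
  against its target — an operational stand-in for "the pattern is not
  discernible".
* Reports use the sample (n−1) standard deviation.

## Benchmark problem sizes

The package's standard benchmark (`nirunet.benchmark`, also what
`scripts/acceptance.py` runs) simulates 1,500 pairs at 96×96, splits
70/15/15, and trains `tiny96` for up to 15 epochs at batch 25 — about 38
GFLOP per training step, a problem size chosen so the whole run fits in
tens of minutes on a single CPU core. Training accepts a wall-clock budget
(15 minutes in the acceptance script, 10 in the test suite) because a
fixed-epoch run's duration varies with the host; the benchmark result
records the epochs completed.
The full-size `main768` overfit check processes its 8-pair batch as
accumulated micro-batches of two — the same full-batch Adam step except
that batch-norm statistics are computed per micro-batch — to keep peak
activation memory within desk-machine limits.

## Known limitations

* The synthetic benchmark is easier than the physical study in some axes
  (perfect registration, homogeneous thickness) and harder in others
  (severe 8 px PSF at 96² resolution); absolute metric values are not
  comparable to the physical study's, only orderings are.
* FSIM agreement is checked against an internal transcription, not a
  third-party implementation.
* The engine is CPU-bound; full-size (200×200, channels to 768) training
  at realistic epoch counts is out of reach without GPU hardware — the
  full-size check in the test suite is bounded by its wall-clock allowance
  and documents what it could complete.
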