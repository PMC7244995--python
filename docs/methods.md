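# Methods

## Model

Each video frame is processed independently (no temporal context), so an
encoded video is an ordered sequence of per-frame latent codes.

**Encoder.** `n_blocks` = 5 dense convolutional blocks. Block *i* applies a
same-padded convolution (kernel 5) with `initial_filters · 2^(i−1)` output
filters, batch normalization and a leaky rectifier (slope 0.2), concatenates
the block input to this sub-block output (the dense skip connection), and
downsamples with a stride-2 2×2 convolution. Every block therefore halves
the spatial resolution and doubles the feature depth: with 8 initial
filters and 256×256 input the ladder is 128²×8 → 64²×16 → 32²×32 → 16²×64 →
8²×128. The final map is globally average-pooled and two affine heads
predict the mean and log-variance of a diagonal Normal over the
`code_length` = 256 latent dimensions. The head's form (pool + affine) is a
design choice: the doubling ladder alone ends at depth 128 and does not
determine how the 256-dimensional code is produced.

**Sampling.** Reparameterization: `z = μ + exp(log σ²/2) ⊙ ε`, `ε ~ N(0, I)`.
One stochastic sample per frame during training; at inference the
deterministic mean is used, making encode→decode a pure function of
(weights, frame).

**Decoder.** An affine map expands the code to the coarsest feature map,
then 5 blocks mirror the encoder in reverse: each block adds a
parameter-free skip path (nearest-neighbour 2× upsampling followed by
grouped channel averaging to the target depth) to a stride-2 transposed
convolution (kernel 5), doubling resolution and halving depth; inner blocks
use batch-norm + leaky ReLU, the final block maps to the image channels
through a sigmoid so outputs lie in [0, 1]. Variance is parameterized as
log-variance throughout for numerical stability.

**Provenance.** Every `CodeSequence` header carries a fingerprint (SHA-256
over configuration, weights and batch-norm statistics, truncated to 16 hex
digits); decoding refuses codes produced by a different model.

## Objective

`L = (1 − MS-SSIM(x, x̂)) + β · KL(q(z|x) ‖ N(0, I)) / code_length`, β = 1
by default. The KL term is normalized by code length so the two terms stay
on comparable scales; the combination rule and β are exposed in
`LossConfig`.

SSIM uses Gaussian-weighted local statistics (window 11, σ = 1.5, valid
padding), constants C1 = (0.01·L)², C2 = (0.03·L)² with data range L = 1,
computed per channel (including the depth channel) and averaged. MS-SSIM
multiplies contrast–structure terms over dyadic scales obtained by 2×2
average pooling, applying the luminance term only at the coarsest scale,
with the published five-scale weights normalized to sum exactly to 1 (the
printed values sum to 1.0001). Scales the input resolution cannot support
(downsampled size < window) are dropped automatically with the remaining
weights renormalized: 64×64 inputs use 3 scales, 256×256 all 5. Before the
fractional-power combination, per-scale terms are clamped at 1e-6; negative
contrast–structure values (possible on adversarial pairs) are treated as
zero similarity.

## Training

Adam at learning rate 0.001 (the learning rate is a stated hyperparameter;
the optimizer itself and batch size 16 are package choices, both exposed).
Videos are split 90/10 into train/validation **by video**, so held-out
frames always come from unseen videos. Training aborts with the offending
epoch/step on a non-finite loss. Checkpoints are NumPy `.npz` archives with
the configuration embedded; save → load → evaluate is bit-identical.

The whole stack, including reverse-mode automatic differentiation for
convolution, transposed convolution, batch normalization and the MS-SSIM
loss, is implemented on NumPy in `privvae.autodiff`/`privvae.nn`. Gradients
of every primitive are validated against central finite differences in the
test suite; the transposed convolution is additionally checked to be the
exact adjoint of the forward convolution.

## Synthetic data

The generator emulates the standardized finger-to-nose recording: eyes
closed, arm abducted, fingertip brought to the nose. Everything is a pure
function of spec + seed.

- **Kinematics.** Fingertip path = linear interpolation start → nose
  + sinusoidal tremor perpendicular to the path
  (`amplitude · sin(2π · frequency · t/n)`, 3 cycles per reach)
  + isotropic Gaussian jitter + occasional along-path overshoot past the
  nose. Severity schedule per grade g: amplitude = 2g px, jitter SD =
  0.5g px (at 64×64, scaled with resolution), overshoot probability = 0.1g.
  Grade 0 is exactly the straight line; mean perpendicular path deviation
  increases strictly with the grade — the ordinal structure the clinical
  scale implies. The first point equals the start exactly; the final jitter
  draw is norm-clipped to one SD so the last point stays within
  jitter + tremor of the nose.
- **Rendering.** An arm segment of per-subject thickness and skin tone is
  drawn from a fixed shoulder anchor to the fingertip over a per-subject
  low-contrast background texture, with a dark nose marker. The optional
  4th channel is a synthetic depth map (background 0, arm at the subject's
  depth offset, fingertip raised 0.3 toward the camera): no real depth
  sensor is modelled; the channel exists to exercise the RGB-D path.
  Intensities are quantized to the 8-bit grid so PNG round trips are
  bitwise lossless. Coordinates are (row, col), origin top-left, 0-based.
- **Raters.** A simulated rater emits
  `clip(round(g + bias + N(0, miscode_sd)), 0, 4)` and replaces it with the
  not-ratable marker with a fixed probability. This Gaussian-discretized
  model admits an exact confusion matrix, which the tests use to verify
  that estimated kappas recover the analytically implied value.
- **Defaults.** 30 frames per video at 64×64 (desk scale; 256×256 available
  via configuration). Clip length and frame rate of the real recordings are
  not standardized anywhere the package could inherit from, so 30 frames is
  a package choice.

What passing tests on this generator do **not** show: performance on real
video (lighting, camera noise, cluttered scenes, articulated bodies,
real depth sensors) or privacy against a determined re-identification
attack; the codes are unreadable to humans, which is a weaker property than
cryptographic protection.

## Agreement statistics

Linearly weighted Cohen kappa: κ = 1 − Σw·O / Σw·E with w_ij = |i − j|
(quadratic weights available as an option), O the observed 5×5
cross-tabulation and E the outer product of its marginals. Computation is
delegated to scikit-learn over the fixed category set {0..4}; a brute-force
double-loop oracle in the tests independently reconstructs O, E and w.

- **Not-ratable handling** is pairwise-complete: a (video, rater) pair
  enters a kappa only if both compared ratings are actual grades; excluded
  counts are reported.
- **Undefined kappa** (both raters constant on the same single category,
  so chance correction has no information) is raised as an explicit
  `KappaUndefinedError`, never coerced to a number.
- **Multi-rater summary** = unweighted mean of all pairwise weighted kappas
  (Light's kappa); pairs with fewer than two shared ratable videos are
  flagged and excluded from the mean.
- **Interpretation bands**: ≤0 chance or worse, (0, 0.2] slight, (0.2, 0.4]
  fair, (0.4, 0.6] moderate, (0.6, 0.8] substantial, (0.8, 1] almost
  perfect; the conventional printed ranges (0.21–0.4 etc.) are closed
  upward so every value in [−1, 1] maps to exactly one band.
- **Mean rating difference** averages (original − decoded) over all jointly
  ratable (video, rater) cells; per-rater-then-per-video averaging would be
  an alternative aggregation, reported values use the joint mean.

## Problem sizes used by the test suite

Unit tests run at 32×32 with a couple of epochs. The acceptance suite
trains the 64×64 RGB-D configuration on 200 frames (10 videos × 20 frames,
5 subjects) for 20 epochs at batch size 16 — the desk-scale setting at
which learning progress, validation improvement and latent phase structure
are asserted. The architecture contract is checked at the full published
256×256 configuration (forward pass only).

## Known limitations

- CPU-only NumPy training: desk-scale runs take minutes; the full
  256×256/400-epoch configuration is supported by the code and
  configuration surface but impractical without accelerator support.
- Per-frame coding ignores temporal structure by design.
- PNG frame sequences are the only video format; container formats (mp4
  etc.) would require an ffmpeg-backed reader.
- Batch statistics: batch-norm uses running estimates at inference;
  training with batch size 1 is allowed but gives degenerate batch
  variance.
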