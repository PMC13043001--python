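# Methods

## The picking model

A micrograph is treated as a single-channel real-valued image. The
pipeline estimates, per pixel, the probability that it belongs to a
particle projection (semantic map), proposes candidate instances, and
keeps only candidates on which both views agree.

### Denoising

Cryo-EM noise is approximately additive and pixel-independent at the
scales that matter for picking, which is what both stages assume.

**Zero-shot Noise2Noise.** Two half-resolution siblings are formed with
fixed 2×2 diagonal-averaging kernels: each tile `[[a,b],[c,d]]`
contributes `(a+d)/2` and `(b+c)/2`. Under pixel-independent noise the
siblings share signal but have independent noise, so a network trained
to map one to the other learns the noise. We fit, per image, a two-layer
3×3 convolutional network (width 48) predicting the noise map, with the
residual loss `½(‖D₁−f(D₁)−D₂‖² + ‖D₂−f(D₂)−D₁‖²)` plus a consistency
term that pulls `Dᵢ − f(Dᵢ)` toward the pair-downsampled full-image
estimate `D(x − f(x))`. The consistency target is held fixed
(stop-gradient) and refreshed every 10 steps — a target-network
formulation that keeps the cost of the full-resolution branch out of
every backward pass without changing what the loss asks for. Adam,
lr 5·10⁻³, 1000 steps by default (300 in the benchmarks); the image is
standardized before fitting and restored after; the network is discarded
per image. Deterministic per seed.

**Classical chain.** Gaussian blur (σ = 1), non-local means with filter
strength 0.8·σ̂ (σ̂ from the median absolute deviation of the 3×3
Laplacian response, which has variance 20σ² under iid noise), Wiener
(5×5), CLAHE (clip 2.0 in the OpenCV convention = clip fraction 0.02,
8×8 tiles), then a guided filter (r = 8, ε = 10⁻²) that takes the CLAHE
image as guide and the pre-CLAHE denoised image as input — local
contrast steers the smoothing without re-amplifying noise. Every mode
ends min-max scaled to [0, 1] because the network consumes bounded
inputs; a constant image maps to zeros.

Orderings: A1 none, A2 classical only, A3 ZS-N2N only, A4 classical →
ZS-N2N, A5 ZS-N2N → classical (default: the unsupervised stage removes
broadband noise the classical chain would otherwise smear into
structure).

### Segmentation network

Four encoder stages at strides 4/8/16/32. Two encoders share the
interface: `pvt_like` (overlapping patch embeddings, one pre-norm
transformer block per stage with spatial-reduction attention at ratios
8/4/2/1 and a convolutional MLP) and `tiny_cnn` (strided 3×3
convolutions, channels 8/16/32/64), the desk-scale default — it trains
from scratch in minutes on one core and exercises every other module
identically.

*Bottleneck:* four parallel branches — 3×3 convolutions at dilation 1,
3 and 5 plus a global-average branch — concatenated and fused by a 1×1
convolution back to the stage width. Requires a bottleneck grid of at
least 5×5, i.e. input side ≥ 160.

*Skip gates:* each skip passes a Global–Local ECA block:
`out = DWSepConv(x) + x ⊙ σ(Conv1D_k(GAP(x)))` with the depthwise-
separable path bias-free (zeros map to zeros). The 1D kernel size is the
nearest odd integer to `|log₂C/γ + b/γ|` (γ = 2, b = 1), ties broken
downward — k = 3 at C = 64.

*Decoder:* four ×2 bilinear upsamplings from stride 32. The first three
fuse the ECA-gated skip (concatenate → 1×1 conv), then apply a
wavelet-convolution block with a residual add:
`y = ReLU(h + WTConv(h))`. The block computes an orthonormal DWT
(Haar by default; any orthogonal PyWavelets family, applied as
cross-correlations with periodic boundary so the inverse is exactly the
adjoint), a depthwise 3×3 convolution on each subband (recursing on the
LL chain for `wt_levels` levels), the inverse transform, plus a parallel
spatial 3×3 convolution. With identity subband kernels and a zeroed
spatial path the block is the identity to float precision — the test
suite verifies this and the ≤10⁻⁶ DWT/IDWT round trip against
PyWavelets. The identity residual lives in the decoder fusion, not
inside the block, so the perfect-reconstruction property is testable in
isolation. The head maps the stride-2 features to one logit channel and
upsamples ×2; bilinear taps are border-renormalized so constants are
preserved exactly.

*Deep supervision:* 1×1 heads at the stride-4/8/16 decoder levels,
upsampled to full resolution, entering the loss with weights
μ = (0.4, 0.3, 0.2). Loss weights λ = (1, 1, 0.5) for BCE/Dice/Focal;
Focal uses α = 0.25, γ = 2 (the canonical values; the picking
literature rarely reports them). Probabilities are clamped to
[10⁻⁷, 1−10⁻⁷]; Dice is smoothed by 10⁻⁶. Reduction is the mean over
pixels, then batch.

All parameters live in a reverse-mode autodiff engine over numpy
written for this package; convolution gradients are verified against
central finite differences in the test suite. Weight init: Kaiming for
convolutions; a single config seed makes initialization, batching and
augmentation reproducible bit-for-bit.

### Proposals and collaborative filtering

The default proposer thresholds the semantic map at 0.5, seeds at maxima
of the distance transform with a minimum separation of half the median
equivalent component diameter (scale-adaptive, so touching particles
split), runs watershed, and scores each segment by its mean probability.
A SAM-style backend can be injected instead: its masks and predicted-IoU
scores enter the same contract, deduplicated at mask-IoU > 0.9. Without
externally supplied weights the adapter raises; it never silently falls
back.

The filter cascade, in order:

1. **Confidence** — keep score ≥ τ_conf = 0.80. Comparisons are ≥ so
   boundary values behave deterministically.
2. **Adaptive size** — keep |diagonal − median| ≤ k·σ (k = 2, σ the
   population standard deviation of all current diagonals; skipped below
   3 proposals where the spread is degenerate), plus area ≥ 16 px and
   bounding-box aspect ≤ 2.5. The median is used as the center because
   the contaminants this filter exists for are exactly the outliers that
   corrupt a mean.
3. **Semantic consistency** — IoU ≥ τ_sem = 0.30 between the proposal
   mask and the union of semantic connected components it touches.
   Component-local IoU is the only reading under which a 0.30 threshold
   is meaningful: against the whole foreground of a dense micrograph the
   ratio degenerates to instance area over total foreground.

Survivors become particles: center = mask centroid, radius =
equivalent-area circle radius (√(area/π); half the longer box side is
available as an option), confidence = proposal score. Coordinates map
back to the original frame by per-axis scale factors, radii by the
geometric mean of the two factors (area-preserving under anisotropic
resizes). Centers closer than 0.5·min(radii) keep the higher score —
prompt-grid backends produce near-duplicates. Output is a STAR loop with
`_rlnCoordinateX/Y`, `_rlnAutopickFigureOfMerit` and optionally
`_rlnParticleDiameter` (pixels, or Å when a pixel size is known),
0-based, x = column, y = row, origin top-left — the convention RELION
and CryoSPARC pickers exchange.

## Synthetic scenes

`simdata` renders particles as spherical projections
(intensity ∝ √(1−(d/r)²)), dark against the background as in real
micrographs, radii ~ N(12, 2²) px in a 512² frame, centers rejection-
sampled so gaps stay ≥ 1.1× the radius sum. Contaminants are random-walk
blobs stamped at 1.6–2.4× the mean particle radius — deliberately
size-outlying, irregular objects that bait the size and consistency
filters. Gaussian noise is scaled so variance(particle layer)/variance
(noise) hits the target SNR (0.3 by default, inside the <0.5 regime the
method targets); the measured ratio stays within 10% per scene. Not
modeled: CTF oscillations, ice gradients, structured noise, particle
adhesion, conformational heterogeneity. Green tests on these scenes
certify the machinery — denoising, segmentation, filtering, bookkeeping
— not performance on EMPIAR data.

## Evaluation

A pick is a true positive when its center lies within the ground-truth
particle's radius (one-to-one, greedy in ascending distance; an optimal
bipartite matcher is available and the suite checks greedy never exceeds
it). Precision/recall/F1 follow; with no picks all three are defined as
0. Dice is reported mask-level (thresholded probability map vs the
ground-truth footprint union); a particle-footprint variant exists via
rasterization. PSNR comparisons fit an affine intensity map first, since
the denoising modes each rescale intensities.

## Desk-scale study conditions

The benchmarks are sized for a single CPU core. End-to-end: 40 training
/ 10 test scenes (512², 25 particles, SNR 0.3, 5 contaminants), network
input 256², `tiny_cnn`, classical-chain denoising (A2 — at this noise
level the chain alone reaches the operating point the segmenter needs,
and it keeps the per-image denoiser out of the 50-scene loop), Adam
lr 10⁻³, batch 2, 160² augmented crops (flips/90° rotations), 25 epochs
≈ 400 steps, checkpoint by best validation Dice on a held-out fifth of
the training scenes. Denoising benchmark: 10 seeded 96² scenes at
SNR 0.3, 300 ZS-N2N steps. The full-scale defaults (1024² input,
pyramid-transformer encoder, A5, 1000 steps) remain the config defaults;
nothing in the code is specific to the reduced sizes.

## Known limitations

The numpy engine is single-threaded and eager; at 1024² with the
transformer encoder it is usable for inference but slow for training —
the architecture is faithful, the throughput is not the point.
Long-filter wavelets use periodic boundaries, so decoder features wrap
at image edges (invisible behind zero-padded convolutions in practice).
The classical proposer cannot separate particles whose distance
transform has a single maximum (heavily fused pairs); the SAM backend
exists for exactly that case. The greedy matcher can undercount tp by
one on adversarial geometry (≲5% of random small instances; the optimal
matcher is a flag away). Training determinism holds for a fixed BLAS;
across different BLAS builds bit-identity is not guaranteed, only
statistical equivalence.
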