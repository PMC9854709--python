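# Methods

## Acquisition model

Images are real 2-D magnitudes on the nominal [0, 1] scale. The Fourier
operator is the orthonormal 2-D DFT with the DC component shifted to
the array center (`fftshift(fft2(ifftshift(x), norm="ortho"))`), so
Parseval's identity holds exactly and image and k-space energies are
directly comparable. Retrospective under-sampling multiplies the fully
sampled k-space element-wise by a binary mask; the zero-filled
reconstruction is the magnitude of the inverse transform. The network
consumes and produces magnitude images only — no phase channels, no
multi-coil physics, no data-consistency projection after the network.

## Under-sampling masks

All masks are parameterised by the sampling rate (fraction of k-space
kept; default 0.20, i.e. acceleration factor 5) and a seed. Line masks
select whole phase-encode lines; the default phase-encode axis selects
columns of the stored matrix (vertical lines), configurable via `axis`.

**MCP (mixed center-periphery).** With N lines and rate r, the total
budget is S = round(rN) (half away from zero). Half of it,
s_c = round(rN/2), is a contiguous block centered on the DC line (even
block lengths put the extra line on the low-index side); a quarter,
s_p = round(rN/4), is the outermost lines split evenly between both
edges (odd counts favour the low edge); the remainder s_r = S − s_c −
s_p absorbs all rounding slack and is drawn uniformly at random from
the lines strictly between the center block and the edge blocks. The
composition identity S = s_c + s_p + s_r is exact by construction; the
ones-fraction is within one line of the rate.

**Gaussian variants.** `1dg` draws S lines without replacement with
probability ∝ exp(−d²/2σ²), d the distance to the DC line; `2dg` draws
S·N individual points with the isotropic analogue. The spread is
σ = 0.15·N by default (the design gives no value; 0.15 concentrates
sampling near the center while leaving visible outliers, matching the
usual appearance of variable-density masks). The DC sample is always
included. Sampling without replacement uses Gumbel top-k, which is
exactly equivalent to sequential weighted draws and fully vectorised.

## Network architecture

The channel bookkeeping is fixed by three printed anchors: the stem
produces 32 channels, the first dense block outputs 64, and growth
rate/width double per spatial level from k₁ = 8, f₁ = 64. Each dense
block has four layers; layer L receives F_in + (L−1)k channels,
reduces them to F_in with a 1×1 convolution and produces k new maps
with a 3×3 convolution, each convolution followed by batch
normalisation and ReLU; the block output concatenates its input with
the four k-channel outputs, giving f = F_in + 4k. Encoder block inputs
are therefore F_in(m) = 2^(m−1)·32 and outputs f(m) = 2^(m−1)·64; the
deepest block is entered by 512 feature maps with growth rate 128. (A
figure in the source design labels the deepest block "f₅ = 512"; under
the doubling rule the block's *output* is 1024 = 512 + 4·128, so 512 is
read as the width entering that block — the only reading consistent
with the block identity and the stated 32→64→128→256→512 progression.)

Decoder levels mirror the encoder: 2×2 transposed convolution halving
the channel count, an attention gate on the same-level encoder skip
(gated by the deeper decoder signal), concatenation, a 1×1 reduction to
F_in(m), and the level-m dense block. Attention gates map the skip x
(1×1 convolution, stride 2) and the gating signal g (1×1 convolution)
into an intermediate space of F_x/2 channels (the design asks only for
a "smaller" space), add, ReLU, reduce to one channel, and apply a
sigmoid; the attention map is bilinearly upsampled ×2 and multiplies x.
The bilinear taps are renormalised at the borders so a constant map
upsamples to exactly that constant; a saturated gate (α ≡ 1) is then
exactly neutral, which the tests exploit.

The layer audit counts every learned convolution and transposed
convolution, including the three 1×1 convolutions inside each gate.
The base assembly (stem + 9 dense blocks + 4 transposed convolutions +
4 decoder reductions + head + 12 gate convolutions) yields 94; a
channel-preserving 1×1 transition convolution after each of the three
deepest encoder poolings — a documented convention in the DenseNet
tradition — brings the total to the design's printed 97. The Unet
baseline is the classical five-level two-convolutions-per-level network
and counts 23. Counts are width-independent.

The 1×1 convolutions are implemented with padding 0; the design's
"1 × 1 convolution with padding 1" would enlarge the map and is treated
as a typo. Its 3-D phrasing for gates ("1 × 1 × 1", "trilinear") maps
to the 2-D analogues since the network is 2-D throughout.

## Training

Training minimises the pixel MSE with Adam (β₁ = 0.9, β₂ = 0.999) under
a stepped schedule lr(e) = lr₀·0.95^⌊e/20⌋. Full-scale defaults follow
the reference configuration (lr₀ = 10⁻⁴, batch 8, 2000 epochs); they
are hyperparameters, not constants. One mask, generated once from its
spec, is shared by all samples and epochs (per-sample random masks are
available behind `per_sample_masks`, off by default). Each zero-filled
input is normalised by its own maximum and the target shares that
constant; losses are therefore on the normalised [0, 1] scale (this
affects only the loss scale, not the optimum). Divergence (non-finite
loss) aborts with a diagnostic. The best-validation weights are kept
alongside the final ones; early stopping is not used. Training is
bit-reproducible given the config seed: the backend is pure numpy.

**Desk-scale configuration.** The full-width 256×256 network is far
beyond a CPU test budget, so the demonstration task uses 64×64
phantoms, a width-reduced network (k₁ = 1, f₁ = 8, 4-channel stem — the
same 97-layer topology; counts and invariants are width-independent)
and lr₀ = 10⁻² for 30 epochs, batch 8, with 200 training / 30
validation / 20 held-out test images. With these sizes the training run
in the acceptance suite takes roughly three minutes and gains about
5 dB PSNR over the zero-filled input; the learning rate is higher than
the full-scale default because a 30-epoch budget leaves the small
network far from convergence at 10⁻⁴.

## Metrics

* **SSIM** — uniform 7×7 window, unbiased local covariances, mean over
  valid windows; stabilisers c₁ = (0.01P)², c₂ = (0.03P)² with
  P = max(T) − min(T). The printed source formula repeats c₁ in every
  stabiliser position yet defines c₂; the standard form is implemented.
  Cross-checked against scikit-image to ~1e−7.
* **PSNR** — 10·log₁₀(255²/MSE) on the 8-bit scale; nominal [0, 1]
  images are scaled ×255 (decided from the reference image only, so
  reconstruction overshoot cannot flip a pair's scale). Identical
  images report +inf, capped at 100 dB in batch aggregates.
* **NRMSE** — RMSE divided by the reference's dynamic range. The
  printed denominator "max T − min R" mixes the two images and is
  treated as a typo for the reference range.
* **VIFP** — standard pixel-domain visual information fidelity: four
  scales, Gaussian windows of size 2^(5−j)+1 with σ = size/5, scalar
  gain-plus-noise channel model, visual noise variance 2 (the published
  pixel-domain parameterisation; the source gives no constants).
  Cross-checked against an independent loop-based transcription of the
  published algorithm to 1e−3 on random pairs.

Absolute metric values depend on the intensity convention (the source
tables' scale is unstated), so only identities, orderings and
improvements are asserted — never table values.

## Phantom generator

Phantoms are ellipse composites in the Shepp-Logan tradition: a
skull-like outer ellipse (randomised axes ≈0.72–0.90 of the half-width,
small center/rotation jitter) containing `n_ellipses` random rotated
ellipses with piecewise-constant intensities drawn from
`intensity_range`, Gaussian-smoothed (σ = 1 px) and clipped to [0, 1].
Additive Gaussian noise (default σ = 0.01) is applied to the image
*before* k-space synthesis, so the stored image is the single source of
truth and |IFFT(k)| reproduces it to numerical precision. Every image
is a pure function of (seed, index). Datasets split train/val/test
in the reference study's 100:30:20 proportions (floor, remainder to
train, at least one sample per split).

`generate_volume` emulates a pass through a head: structure size and
brightness follow an elliptical profile along the slice axis, with the
outermost slices holding small, very dim anatomy while the additive
noise floor stays constant. Because NRMSE normalises by the slice's own
dynamic range, border slices reconstruct with visibly larger normalised
error than content-rich central slices — the slice-profile pattern seen
in real volumes.

What the phantoms do **not** model: real anatomy and texture, coil
sensitivities, k-space noise correlations, motion, relaxation contrast.
Passing tests therefore demonstrate that the pipeline removes
sub-sampling aliasing from piecewise-smooth images — not clinical-grade
performance on real brains, which additionally depends on dataset scale
and full-width training.

## Numerical and design notes

* The autodiff backend stores float32 activations; convolutions are
  sums of per-offset BLAS matmuls; gradients of every primitive are
  validated against central finite differences in float64.
* Max-pooling breaks ties by the first maximum (argmax order).
* Batch normalisation: momentum 0.1, ε = 10⁻⁵, running statistics used
  in eval mode; after every convolution except the output head.
* Initialisation is He (fan-in) with a recorded seed; identical seeds
  give bit-identical parameters and outputs.
* PSNR of identical images is +inf by definition; batch reports
  substitute a 100 dB sentinel so means stay finite.
* Degenerate inputs (constant reference for SSIM/NRMSE/VIFP, rates too
  small for a center block, non-finite arrays) raise typed errors
  rather than returning silently wrong numbers.

## Known limitations

Single-coil, Cartesian, magnitude-only; no iterative/data-consistency
reconstruction; the numpy backend is CPU-bound, so full-scale (256×256,
k₁ = 8, 2000-epoch) training is out of reach — the architecture builds
and audits at full width, but training experiments are meant for the
desk-scale configuration. Comparison networks beyond the plain Unet
baseline are out of scope.
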