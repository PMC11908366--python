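# Methods

## Model

The package implements a residual-shifting diffusion model for paired
super-resolution of 2-D image slices.  Both members of a pair live on the
same pixel grid: the low-resolution (LR) image is pre-upsampled onto the
high-resolution (HR) grid with nearest-neighbor interpolation before
anything else happens, and all modeling is done in normalized intensity
units (see *Normalization* below).

**Forward process.**  With residual `e0 = x_LR − x_HR` and a strictly
increasing shifting sequence `β_1 < … < β_T` (increments
`α_t = β_t − β_{t−1}`, `α_1 = β_1`), the Markov kernel is

    x_t = x_{t−1} + α_t e0 + γ √α_t ε,   ε ~ N(0, I),

whose closed-form marginal is `x_t = x_HR + β_t e0 + γ √β_t ε`.  The chain
telescopes: the drift coefficients sum to `β_t` and the per-step variances
sum to `γ² β_t`, so the terminal distribution is `N(x_LR, γ² β_T I)` when
`β_T ≈ 1` — the diffusion ends *at the LR image*, not at pure noise.

**Reverse process.**  The transition `q(x_lo | x_hi, x_HR, x_LR)` between
any two schedule levels `t_hi > t_lo` is the product of two Gaussian
densities and therefore Gaussian, with

    mean = (β_lo/β_hi) x_hi + ((β_hi−β_lo)/β_hi) x_HR,
    var  = γ² (β_hi−β_lo) β_lo / β_hi.

The implementation exposes this *generalized two-level* form rather than
only adjacent steps: the adjacent case reduces to the familiar
`(β_{t−1}/β_t) x_t + (α_t/β_t) x_HR` with variance `γ² α_t β_{t−1}/β_t`,
and the general case is what makes any subsequence of the training schedule
a valid sampling path (verified against a numeric product-of-densities
oracle in the tests).  The sampler initializes `x_T ~ N(x_LR, γ² β_T I)`,
substitutes the network estimate `x̂_HR = g_φ(x_t, x_LR, t)` into the
posterior mean, injects noise scaled by the posterior standard deviation at
every transition except the last, and — because `β_0 := 0` — ends with a
deterministic collapse onto the final estimate.  Consequence, used as a
test anchor: with a perfect denoiser the sampler returns `x_HR` to machine
precision for *any* step subsequence and seed; all reconstruction error is
attributable to the learned denoiser.

**Training objective.**  Each step draws a timestep per batch element
uniformly from `1..T`, forms `x_t` from the marginal, and minimizes
`λ·MSE(g_φ, x_HR) + ℓ_perceptual(g_φ, x_HR)`.  The β-dependent prefactor of
the underlying KL objective is deliberately dropped, and `‖·‖²` is realized
as the per-pixel *mean* squared error so that λ (default 10) keeps its
meaning across image sizes.

## Schedule

Geometric interpolation on a log scale:

    β_1 = (κ/γ)²,   β_t = β_1 · exp(((t−1)/(T−1))^p · log(β_T/β_1)).

Defaults: `T = 15`, `p = 0.3`, `γ = 2`, `κ = 0.04`, `β_T = 0.9999`.  `κ` is
the smallness target `γ√β_1 = 0.04`, which keeps the first diffusion step
visually indistinguishable from the clean image; `p < 1` front-loads the
shift (smaller `p` ⇒ larger interior `β_t` ⇒ noisier intermediate states).
The closed form analytically reduces to `β_1` and `β_T` at the endpoints,
so it is evaluated for all `t` with no special-casing (endpoints are then
pinned exactly against rounding).  Few-step sampling uses evenly spaced
indices in `t` that always include `T` (`S=4` over `T=15` gives
`[1, 6, 10, 15]`); the spacing rule is a package choice, made valid by the
generalized posterior, and `S = 1` degenerates to a single deterministic
collapse through the denoiser.

## Denoiser

`g_φ(x_t, x_LR, t)` is an encoder–decoder with skip connections in which
windowed multi-head self-attention (Swin-style, with cyclic half-window
shifts alternating between blocks) replaces global attention; an ablation
switch (`use_windowed_attention=False`) removes every attention block.
Choices the model family leaves open, fixed here as:

- conditioning by channel concatenation of `x_t` and `x_LR` (standard for
  restoration diffusion and matching the `g_φ(x_t, x_LR, t)` signature);
- sinusoidal embedding of the integer timestep index (schedule-agnostic),
  injected additively per-channel in every residual block;
- attention at the two coarsest resolution levels plus the bottleneck
  (bounds cost; the bottleneck window is shifted);
- zero-initialized output convolution plus a global skip from the LR
  channel, so the untrained network is exactly the identity on its LR input
  and training only learns the correction;
- desk-scale default `base_channels=32`, `depth=3`, `window_size=4`.

The network, its reverse-mode autodiff, and the RAdam optimizer are written
directly on NumPy arrays (channels-last layout; convolution as one GEMM per
kernel offset).  Every primitive's gradient and the end-to-end loss
gradient are validated by central finite differences in the test suite.

## Training

RAdam (β₁=0.9, β₂=0.999) under a linear-warmup-then-cosine learning-rate
schedule, continuous at the junction.  Full-scale defaults follow the
method's published recipe (batch 16, warmup 5,000 steps, initial rate 3e-5
— midpoint of the quoted 2e-5..5e-5 range).  The desk-scale preset used by
the tests and examples (`desk_scale_train_spec`) is batch 8, 2,000 steps,
warmup 200, initial rate 1e-3: runs three orders of magnitude shorter than
the published ones need a proportionally larger rate and shorter warmup to
leave the ramp phase at all.  Timesteps are drawn per-sample rather than
per-batch (lower gradient variance).  Divergent losses raise immediately
with the offending step named.  Checkpoints embed a schedule fingerprint;
sampling with a mismatched schedule is a fatal error because the posterior
coefficients are schedule-dependent.  A separate resumable training state
(weights, optimizer moments, RNG state, pending batch order) reproduces an
uninterrupted trace exactly.

## Perceptual metric

The perceptual term is a feature-space distance through a small *fixed
random* convolutional pyramid (3 levels, 8 channels, SiLU, average pooling;
seed-pinned weights).  Random convolutional features are a classical
baseline for perceptual similarity; the construction guarantees
`d(x, x) = 0` and `d ≥ 0`, needs no external weights, and is differentiable
through the same autodiff stack.  Any callable with the same contract (for
example a pretrained LPIPS wrapper) can be plugged in wherever a
`PerceptualMetric` is accepted, both as a loss term and as a report metric.

## Metrics

- **PSNR** `10·log10(range²/MSE)`; identical images are flagged rather than
  propagating infinity into aggregates.  `data_range` is fixed to the
  normalization interval width (1.0), not per-image maxima, for
  comparability across slices.
- **SSIM** delegates to scikit-image's standard single-scale form (11×11
  Gaussian window, σ=1.5, K1=0.01, K2=0.03).
- **GMSD** is hand-implemented (no installed provider): 1/3-normalized
  Prewitt gradient magnitudes, similarity map
  `(2 m_r m_t + c)/(m_r² + m_t² + c)`, score = its standard deviation.  The
  constant `c = 170` is defined on the 8-bit scale and rescaled by
  `(data_range/255)²`.  Replicated borders; no pre-downsampling.
- Reports aggregate mean ± sample SD (ddof=1) per metric; an optional mask
  restricts PSNR and the SSIM/GMSD maps to foreground (full frame is the
  default, matching the convention that skull-stripped backgrounds are zero
  in both images).

## Synthetic data

Phantoms are composites of soft-edged random ellipses (amplitudes of both
signs, Gaussian-smoothed, optional acquisition noise), min–max scaled into
the intensity range over the foreground and zeroed outside a circular mask
— emulating skull-stripped tissue maps.  Degradation is image-space
block-mean downsampling by integer per-axis factors (×4 brain preset, ×3
prostate preset; `antialias=False` switches to decimation) followed by
nearest-neighbor re-upsampling, chosen over a general resampler for the
exact, testable piecewise-constant block structure.  Train/test splits come
from disjoint seed streams.  What passing tests on phantoms do **not**
show: behavior under MR acquisition physics (bias fields, coil profiles,
k-space artifacts), anatomy-scale structure, or through-plane resolution
loss — slices are independent 2-D images, mirroring the method's stated
2-D-per-slice design.

## Normalization and I/O

NIfTI volumes are normalized to [0, 1] by robust percentile scaling
(0.5/99.5, clipped) — quantitative T1 maps and T2-weighted magnitudes have
heavy-tailed outliers that would otherwise dominate a min–max scale.  The
record computed from the HR volume is applied to *both* members of a pair
so the residual is meaningful, and inverts exactly on non-clipped voxels.
Constant volumes raise a degenerate-scale error.  Axial slices are taken
along the last volume axis.

## Problem sizes

The test suite and examples run at deliberate desk scale: 16–32 px
phantoms, networks of 8–32 base channels, and a single 2,000-step training
run (the largest test, about ten minutes on one CPU core); the Monte-Carlo
forward-consistency check uses 10⁵ draws on an 8×8 pair, and the posterior
oracle 1,000 random scalar instances.  Full-scale presets (batch 16,
5,000-step warmup) are configuration, not separate code paths.

## Known limitations

- 2-D slices only; no inter-slice continuity mechanism.
- The exact layer inventory of the published network is not public; the
  architecture above is an explicit, documented stand-in with the same
  interface and conditioning structure.
- The NumPy stack is single-threaded-CPU oriented; it is not intended for
  full-scale (10⁵-step, 288×288) training.
- Learned/adaptive schedules and measurement-consistency projections are
  out of scope.
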