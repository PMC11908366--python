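# shiftsr

Few-step **residual-shifting diffusion** for MRI super-resolution, in pure
scientific Python (NumPy-based network stack — no GPU or deep-learning
framework required).

## The problem and the model

Super-resolution (SR) reconstructs a high-resolution (HR) image `x_HR` from a
low-resolution (LR) acquisition `x_LR` (pre-upsampled to the HR grid with
nearest-neighbor interpolation, so both live on the same pixel lattice).
Standard diffusion models solve this by denoising from pure Gaussian noise
over hundreds of steps.  Here the forward process instead *shifts* the HR
image toward its LR counterpart through the residual

```
e0 = x_LR − x_HR
```

along a monotone shifting sequence `β_1 < … < β_T` with increments
`α_t = β_t − β_{t−1}`:

```
q(x_t | x_{t−1}, x_LR) = N(x_t ; x_{t−1} + α_t e0 , γ² α_t I)
q(x_t | x_HR, x_LR)    = N(x_t ; x_HR + β_t e0 , γ² β_t I)        (marginal)
```

so the terminal distribution is centered on the LR image, `N(x_LR, γ² β_T I)`,
rather than on zero.  The reverse transition between schedule levels
`t_hi > t_lo` is the product of two Gaussians and hence Gaussian:

```
mean = (β_lo/β_hi) x_t + ((β_hi−β_lo)/β_hi) x̂_HR ,
var  = γ² (β_hi−β_lo) β_lo / β_hi ,
```

with the clean-image estimate `x̂_HR = g_φ(x_t, x_LR, t)` supplied by a
windowed-attention U-net trained with the composite objective
`L = λ‖g_φ − x_HR‖² + ℓ_perceptual` (λ = 10).  Because `β_0 = 0`, the final
transition collapses deterministically onto the estimate — which is what
makes sampling in as few as **4 steps** (against a 15-step training
schedule) exact for a perfect denoiser.  The schedule is geometric:
`β_1 = (κ/γ)²` with smallness target `γ√β_1 = κ = 0.04`, `β_T = 0.9999`,
growth exponent `p = 0.3`, `γ = 2`.

The package provides: the schedule (`shiftsr.schedule`), forward/posterior
kernels and the sampler (`shiftsr.diffusion`), the denoiser with a NumPy
autodiff stack (`shiftsr.nn`), the training loop with RAdam and
warmup+cosine learning rate (`shiftsr.training`), PSNR/SSIM/GMSD/perceptual
metrics (`shiftsr.metrics`), a paired-phantom generator
(`shiftsr.synthetic`), NIfTI I/O (`shiftsr.io_data`), an sklearn-style
estimator (`ResidualShiftSR`), and a CLI (`shiftsr`).

## Worked example

```python
import numpy as np
import shiftsr as s

sched = s.build_schedule()                      # T=15, p=0.3, γ=2, κ=0.04, β_T=0.9999
print(sched.betas[0], sched.betas[-1])          # 0.0004 0.9999

# paired 32x32 phantoms at x4 degradation
train, test = s.make_split(16, 4, s.PhantomSpec(size=32), s.DegradeSpec(4, 4), seed=7)

# a perfect denoiser recovers x_HR exactly in 4 steps (the method's key identity)
steps = s.select_sampling_timesteps(sched, 4)   # [1, 6, 10, 15]
pair = test[0]
out = s.reverse_sample(pair.lr, lambda x, lr, t: pair.hr, sched, steps, rng_seed=0)
print(np.abs(out - pair.hr).max())              # 0.0

# train a small model and super-resolve
est = s.ResidualShiftSR(base_channels=16, depth=2, total_steps=300,
                        warmup_steps=30, batch_size=4, seed=0)
est.fit(np.stack([p.lr for p in train]), np.stack([p.hr for p in train]))
X_test = np.stack([p.lr for p in test])
print(f"LR baseline {np.mean([s.psnr(p.hr, p.lr) for p in test]):.2f} dB, "
      f"model {est.score(X_test, np.stack([p.hr for p in test])):.2f} dB")
```

A 300-step run of this example printed `LR baseline 20.68 dB, model 23.92 dB`
— already well above the nearest-neighbor input; the full desk-scale recipe
(2,000 steps, `base_channels=32`, `depth=3`, 64 training phantoms) reached
27.7 dB against an 18.8 dB baseline on 20 held-out phantoms (the test suite
asserts a ≥ 1 dB margin).  The CLI drives the same pipeline from
a shell: `shiftsr simulate → train → sample → evaluate`, plus
`shiftsr schedule-dump` for the β/α table.

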