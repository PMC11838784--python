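# sparsect

**When are diffusion priors helpful in sparse-view CT reconstruction?**

`sparsect` is a desk-scale, fully reproducible pipeline for a question that
matters in low-dose CT: as the number of X-ray projections shrinks, at what
point does a learned diffusion prior beat the classical regularizers — and
when does it stop helping?  The package targets researchers studying
reconstruction priors and evaluation methodology, with thoracic fat
quantification as the downstream task.

It provides:

* seeded **chest-like CT phantoms** with HU-labeled compartments (fat ring
  at −100 HU inside the −150..−50 HU fat window),
* a **parallel-beam projector** A with an exact matched adjoint,
* **classical reconstructions** — Tikhonov (min ‖Ax−b‖² + λ‖x‖²) by
  conjugate gradients and total variation (min ‖Ax−b‖² + λ·TV(x)) by
  monotone FISTA with a Chambolle prox,
* a **diffusion prior** — squared-cosine DDPM (T = 1000) with a small
  numpy ε-predictor and measurement-guided sampling: over 50 steps the
  predicted clean image x̂₀ is projected, and λ·∇_{x̂₀}MSE(A x̂₀, b) with
  λ = 0.1 is subtracted before each ancestral update,
* **metrics** — PSNR, SSIM, fat content accuracy, fat dice,
* the **dominance interval** I = [LB, UB]: LB from the plateau "corner" of
  the candidate's metric curve (or a threshold τ_M), UB as the largest
  nproj where a one-sided Mann-Whitney U-test still finds the candidate
  better than the baseline at τ_p = 0.05, with U/(n₁n₂) estimating
  P(M₁ > M₂).

See `docs/methods.md` for the full model description and design choices.

## Worked example

`examples/05_tiny_experiment.py` trains a diffusion prior on 200 seeded
32² phantoms, then reconstructs 6 held-out slices with all three priors at
4 projection counts:

```
median PSNR (dB) by method and projection count:
nproj          5      10     45     180
method
DIFFUSION    18.84  18.87  18.85  18.85
L1_TV        21.17  25.64  30.56  35.89
L2_TIKHONOV  17.65  21.23  27.37  32.16

dominance intervals (diffusion vs each classical baseline):
         metric    baseline  LB   UB  p_at_UB
        psnr_db L2_TIKHONOV   5  5.0 0.046537
           ssim L2_TIKHONOV   5  5.0 0.001082
fat_content_acc       L1_TV   5  5.0 0.001082
fat_content_acc L2_TIKHONOV   5 10.0 0.006453
       fat_dice L2_TIKHONOV   5  5.0 0.001082
```

Reading the numbers: classical priors keep improving as projections are
added (21 → 36 dB for TV), while the guided-diffusion curve is flat from 5
projections on — the prior dominates what the data can say.  The dominance
table makes that trade-off precise: at 5–10 projections diffusion is
statistically better than Tikhonov on pixel, structural, and fat metrics
(UB = 5–10 with p ≤ 0.05), and the advantage disappears once projections
are "sufficient".  Absolute values are specific to this tiny score network
and phantom family.

The other examples are single-capability walkthroughs: phantom generation
(`01`), classical reconstruction (`02`), guided sampling on an analytic
Gaussian testbed where the optimal noise predictor and the posterior mean
are closed-form (`03`), and the dominance interval on constructed curves
(`04`).  A thin CLI wraps the same functions:
`sparsect phantoms|run|bounds|plot`.

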