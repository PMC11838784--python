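# Methods

## Problem setting

Sparse-view CT reconstructs an attenuation image x (Hounsfield units) from a
sinogram b = Ax of line integrals taken at `nproj` projection angles.  When
`nproj` is small the problem is ill-posed and the answer depends on the
prior.  This package compares three priors on identical synthetic data:

* **Tikhonov (L2):** min ‖Ax − b‖² + λ‖x‖² (optionally λ‖∇x‖²),
* **Total variation (L1):** min ‖Ax − b‖² + λ·TV(x),
* **Guided diffusion:** an unconditional denoising-diffusion prior steered by
  the gradient of the sinogram-consistency loss,

and scores every reconstruction by PSNR, SSIM, and two downstream fat
metrics, then locates the projection-count interval I = [LB, UB] where one
prior statistically dominates another.

## Synthetic phantoms

`phantoms.generate_chest_phantom` builds a seeded 2D chest-like slice:
elliptical body, a thin soft-tissue rind, a subcutaneous fat ring, two
lungs, a spine blob and rib-like bone dots.  Compartment means are standard
CT values (air −1000, lung −800, fat −100, soft tissue +40, bone +400 HU);
per-pixel Gaussian jitter (default sd 10 HU) adds texture and a sub-pixel
Gaussian blur (default sigma 0.15 px) softens edges toward partial-volume
behavior.  Geometry (body axes, fat thickness, lung placement) is randomized
per seed.  Two constraints drove the defaults:

* the fat ring must read almost entirely inside the −150..−50 HU window
  (fat mean −100 with sd-10 jitter leaves 5 sd of margin on either side);
* windowing the noiseless phantom must recover the ground-truth fat label
  with dice ≥ 0.99, which caps the edge blur below the pixel scale (larger
  blur mixes fat/soft and soft/lung boundary values into or out of the
  window).

Dataset members derive child seeds via `SeedSequence([base_seed, index])`,
so a dataset is reproducible from `(spec, seed)` and members never collide
with other seed streams.  What the phantoms deliberately do **not** model:
3D anatomy, realistic organ shapes, scanner table artifacts, beam hardening
or detector noise (optional additive Gaussian sinogram noise is available
but off by default).  Passing tests therefore demonstrate correctness of
the pipeline's machinery on piecewise-smooth anatomy with a well-defined
fat window — not clinical performance.

## Projector

`projection.LinearProjector` is a 2D parallel-beam operator assembled as a
sparse matrix with a Joseph-style kernel: each ray steps through the image
along its dominant axis and deposits linearly interpolated weights scaled by
the slab intersection length (units HU·mm via `spacing_mm`).  Defaults:
angular span π (complete for parallel-beam data), ndet = image size,
detector spacing = pixel spacing.  Backprojection is the matrix transpose,
so the adjoint identity holds to float precision — the property the CG
solver, FISTA, and the guidance gradient all rely on.  Accuracy checks: disk
projections match the analytic chord profile to within 2% of the peak over
resolved rays (tangent rays are limited by object pixelization, not by the
operator, and are validated against a dense line-sampling integrator
instead); detector sums conserve image mass to <1% at every angle.

"360 projections" is interpreted as 360 uniform angles over [0, π).

## Classical solvers

All solvers run on the normalized [−1, 1] intensity scale the diffusion
model uses, so a given λ means the same thing for every prior; results are
mapped back to HU for scoring.

**Tikhonov:** hand-rolled conjugate gradients on the normal equations
(AᵀA + λP)x = Aᵀb with P = I (default) or the graph Laplacian ∇ᵀ∇ for a
smoothness penalty.  The quadratic objective is logged each iteration and is
monotone by CG construction; stopping at relative normal-equation residual
1e−6 or `n_iters`, with a `converged` flag rather than an exception.

**TV:** monotone FISTA (the accepted iterate never increases the objective)
with gradient steps of size 1/(2‖A‖²) from a power-method estimate, and the
isotropic-TV proximal operator (forward differences, replicate boundary)
computed by Chambolle's dual projection with step τ = 1/8 and 30 inner
iterations.  The solver runs exactly `n_iters` outer iterations.  λ = 0
reduces to plain least squares but, as a first-order method, needs ~4000
iterations to match CG to 0.1% on a 32² instance.

## Diffusion prior

**Schedule.** Squared-cosine: ᾱ_t = f(t)/f(0) with
f(t) = cos²(((t/T + s)/(1 + s))·π/2), T = 1000, s = 0.008, evaluated on the
grid t = 0..T−1 (so ᾱ_0 = 1 exactly); β_t = 1 − ᾱ_t/ᾱ_{t−1} clipped to
[1e−12, 0.999].

**Score network.** A deliberately small fully-connected ε-predictor:
sinusoidal time embedding (dim 32), two SiLU hidden layers (width 80), and a
time-gated skip connection ε̂ = g(t)·x_t + MLP(x_t, t), ~174k parameters at
32².  The skip is essential at this scale: the white-noise component of ε is
full-rank and cannot pass through a narrow bottleneck, while the anatomy
correction the MLP must model is low-dimensional.  Training minimizes
E‖ε − ε̂(√ᾱ_t x₀ + √(1−ᾱ_t) ε, t)‖² with Adam (lr 2e−3, batch 32) in pure
numpy — bit-deterministic for a fixed seed.  Any object with
`predict_eps(x_t, t)` can replace it, including the closed-form predictor
for a Gaussian prior used as a test oracle.

**Sampling.** Ancestral DDPM respaced to 50 uniform-stride steps ending at
t = 0.  Per-step variance is σ_t² = β_t (the larger of the two standard
choices): on the analytic Gaussian testbed the posterior-lower-bound
variance under-disperses samples by ~25%, while β_t reproduces prior
variance within 15%.  `clip_x0` (off by default, on in the experiment
pipeline) clips the clean-image estimate to [−1, 1]; it is a no-op for a
well-calibrated predictor but prevents divergence of imperfect learned
models, whose x̂₀ error is amplified by 1/√ᾱ_t at early steps.  The same
amplification leaves trained desk-scale models with a small systematic
sample-moment bias (~0.02–0.03 on the [−1, 1] scale even at training loss
5e−4), which the tests bound at 0.05 as a frozen regression value.

**Guidance.** At each step: x̂₀ = (x_t − √(1−ᾱ_t) ε̂)/√ᾱ_t, then
x̂₀ ← x̂₀ − λ_guid · ∇_{x̂₀} MSE(A x̂₀, b) with λ_guid = 0.1, before the
ancestral update is formed from the corrected x̂₀.  The gradient is
(2/m)·Aᵀ(A x̂₀ − b) with m the sinogram size; no per-step renormalization.
Taking the gradient with respect to (and applying it to) the predicted clean
image is the posterior-sampling reading of measurement guidance; perturbing
x_t instead is possible via the same config surface but is not the default.
With guidance weight 0 the sampler is bit-identical to unconditional
sampling at the same seed.

## Metrics

* PSNR over a fixed 2000-HU evaluation range (comparable across slices),
  capped at 100 dB for exact matches.
* SSIM with the standard parameterization: Gaussian window sigma 1.5
  (11×11 support), K1 = 0.01, K2 = 0.03, population covariances
  (scikit-image backend).
* Fat mask: −150 ≤ HU ≤ −50, inclusive at both endpoints, always computed
  on the HU scale after inverse normalization.
* Fat content accuracy: percent of pixels whose fat/non-fat classification
  agrees.  Fat dice: 2|A∩B|/(|A|+|B|), with both-empty defined as 1
  (perfect agreement on absence).  Accuracy and dice deliberately decouple:
  a small mislocalized fat region keeps accuracy high while dice collapses.

## Dominance interval

Per (metric, method, nproj) the per-slice values form a distribution,
summarized by the median and the 0.05/0.95 quantiles (linear-interpolation
definition).  The interval I = [LB, UB] of candidate-over-baseline
dominance is computed as:

* **LB** — either the smallest nproj whose candidate median passes a user
  threshold τ_M (inequality flipped for decreasing metrics), or the
  "corner" where the median first reaches 95% of the plateau level (median
  of medians over the top quartile of nproj values; the rule presumes
  positive metric scales).  A corner that only lands on the last grid point
  while the curve is still changing is flagged as not plateaued.
* **UB** — the largest nproj whose one-sided Mann-Whitney U-test (candidate
  better than baseline) has p ≤ τ_p (default 0.05).  U/(n₁n₂) is recorded
  per nproj as an estimate of P(M₁ > M₂).

The U-test uses the exact null distribution for no-tie samples with
n₁+n₂ ≤ 12 and the normal approximation with midrank tie correction
otherwise (scipy backend; exactness is cross-checked against brute-force
rank enumeration in the tests).  Slices are shared across methods, but the
comparison is intentionally unpaired; a paired Wilcoxon variant is available
behind a flag.  Negating all samples and flipping the declared direction
yields the same interval (duality), and raising τ_M (τ_p) never decreases
LB (UB).  No multiple-testing correction is applied across metrics.

## Experiment orchestration

`run_experiment` sweeps (slice × nproj × method): noiseless sinograms are
simulated per projection count on the normalized scale, each method
reconstructs, metrics are computed in HU, and curves/bounds are summarized
to CSV (plus a resolved-config JSON).  Training, evaluation, and sampler
seeds come from disjoint `SeedSequence` streams of the experiment seed, so
the evaluation set never overlaps the diffusion training set and reruns are
byte-identical.  One trained checkpoint is reused across all nproj.
`grid_search_lambda` picks regularization/guidance weights by lowest mean
image MSE at the fully-sampled setting (360 projections), ties toward the
smaller value; on noiseless data it correctly prefers the weakest
regularization.

Default problem sizes are chosen for single-CPU work: 32² phantoms, 200
training slices, 300 training epochs (~10 s), 10 evaluation slices, and the
nproj grid {2, 5, 7, 10, 15, 25, 40, 60, 90, 180, 360} (tests and the
acceptance script use the {5, 10, 45, 180} subset).  At these sizes the
end-to-end sweep reproduces the qualitative signature the statistics are
built to quantify — classical PSNR climbing with nproj while the diffusion
curve plateaus — but absolute values depend on the tiny score network and
phantom family and carry no clinical meaning.

## Known limitations

* Parallel-beam geometry only; fan/cone-beam and helical scans are out of
  scope.
* The score network is a proof-of-scale MLP, not a U-Net; unconditional
  sample fidelity is limited and guided reconstructions plateau well below
  classical priors at high nproj.
* Phantoms are 2D and stylized; no claim transfers to clinical CT without
  retraining and revalidation on real data.
* The corner rule assumes positive metric scales and a declared metric
  direction.
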