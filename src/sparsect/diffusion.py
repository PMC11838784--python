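"""Denoising-diffusion prior and measurement-guided sampling.

A small unconditional DDPM works on normalized [-1, 1] images: squared-cosine
noise schedule over T=1000 timesteps, an epsilon-predicting score network, and
ancestral sampling respaced to a short (default 50-step) schedule.  Guidance
follows the posterior-sampling recipe: at every step the clean-image estimate
x0_hat is projected through the CT operator, the mean-squared error against
the observed sinogram is computed, and its gradient with respect to x0_hat
(scaled by the guidance weight, default 0.1) is subtracted from x0_hat before
the ancestral update.

The score network here is a deliberately small fully-connected
epsilon-predictor (sinusoidal timestep embedding, two hidden layers, SiLU,
<= 200k parameters at 32 x 32) trained with Adam by explicit numpy
backpropagation; any object with ``predict_eps(x_t, t)`` can stand in for it,
including the closed-form Gaussian-prior predictor used as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .projection import LinearProjector, Sinogram
from .classical import ReconstructionResult, Method

_BETA_MIN = 1e-12
_BETA_MAX = 0.999


@dataclass(frozen=True)
class NoiseSchedule:
    """Forward-process arrays over T timesteps: x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps."""

    T: int
    alpha_bar: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        ab = np.asarray(self.alpha_bar, float)
        be = np.asarray(self.beta, float)
        if self.T < 2 or len(ab) != self.T or len(be) != self.T:
            raise ValueError("invalid schedule arrays")
        if np.any(ab <= 0) or np.any(ab > 1) or np.any(np.diff(ab) >= 0):
            raise ValueError("alpha_bar must be strictly decreasing within (0, 1]")
        if np.any(be <= 0) or np.any(be >= 1):
            raise ValueError("beta must lie in (0, 1)")
        object.__setattr__(self, "alpha_bar", ab)
        object.__setattr__(self, "beta", be)


def build_cosine_schedule(T: int = 1000, s_offset: float = 0.008) -> NoiseSchedule:
    """Squared-cosine schedule: abar_t = f(t)/f(0), f(t) = cos^2(((t/T+s)/(1+s)) pi/2).

    Evaluated on the grid t = 0..T-1 so abar_0 = 1 exactly; betas are the
    per-step ratios 1 - abar_t/abar_{t-1}, clipped to [1e-12, 0.999].
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if s_offset <= 0:
        raise ValueError("s_offset must be positive")
    t = np.arange(T)
    f = np.cos(((t / T + s_offset) / (1 + s_offset)) * np.pi / 2.0) ** 2
    alpha_bar = f / f[0]
    beta = np.empty(T)
    beta[1:] = 1.0 - alpha_bar[1:] / alpha_bar[:-1]
    beta[0] = 1.0 - alpha_bar[0]
    beta = np.clip(beta, _BETA_MIN, _BETA_MAX)
    return NoiseSchedule(T, alpha_bar, beta)


def predict_x0(x_t: np.ndarray, eps_hat: np.ndarray, t: int, schedule: NoiseSchedule) -> np.ndarray:
    """Clean-image estimate x0_hat = (x_t - sqrt(1-abar_t) eps_hat)/sqrt(abar_t)."""
    if not 0 <= t < schedule.T:
        raise ValueError(f"timestep {t} outside [0, {schedule.T})")
    ab = schedule.alpha_bar[t]
    return (x_t - np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(ab)


# ---------------------------------------------------------------------------
# score models


@dataclass
class AnalyticGaussianScore:
    """Exact epsilon-predictor for the prior x0 ~ N(mean, var * I).

    Under the forward process, x_t ~ N(sqrt(abar_t) mean, (abar_t var + 1 -
    abar_t) I), and the optimal predictor is affine in x_t:
    eps_hat = (x_t - sqrt(abar_t) mean) * sqrt(1-abar_t) / (abar_t var + 1 - abar_t).
    Used as a closed-form testbed for guided sampling (no training involved).
    """

    mean: np.ndarray
    var: float
    schedule: NoiseSchedule

    def __post_init__(self):
        if self.var <= 0:
            raise ValueError("var must be positive")
        self.mean = np.asarray(self.mean, float)

    @property
    def image_size(self) -> int:
        return self.mean.shape[0]

    def predict_eps(self, x_t: np.ndarray, t: int) -> np.ndarray:
        ab = self.schedule.alpha_bar[t]
        return (x_t - np.sqrt(ab) * self.mean) * np.sqrt(1.0 - ab) / (ab * self.var + 1.0 - ab)


def _time_embedding(t_frac: np.ndarray, dim: int) -> np.ndarray:
    """Sinusoidal embedding of t/T, shape (batch, dim)."""
    half = dim // 2
    freqs = np.exp(np.linspace(0, np.log(1000.0), half))
    ang = t_frac[:, None] * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


def _silu(z):
    sig = np.empty_like(z)
    pos = z >= 0
    sig[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    sig[~pos] = ez / (1.0 + ez)
    return z * sig, sig


class MLPScoreModel:
    """Fully-connected epsilon-predictor with sinusoidal time conditioning.

    Two SiLU hidden layers of width ``hidden`` plus a time-gated skip from
    the noisy input straight to the output: eps_hat = g(t) * x_t + MLP(x_t, t).
    The skip carries the high-dimensional white-noise component (which a
    narrow bottleneck cannot transmit); the MLP models the low-dimensional
    anatomy correction.  At 32 x 32 with the default width 80 the parameter
    count is ~174k.  Weights are float64 and all arithmetic is plain numpy,
    so training and sampling are bit-deterministic for a fixed seed.
    """

    def __init__(self, image_size: int, hidden: int = 80, t_embed_dim: int = 32,
                 T: int = 1000, seed: int = 0):
        self.image_size = image_size
        self.T = T
        self.t_embed_dim = t_embed_dim
        d = image_size * image_size
        rng = np.random.default_rng(np.random.SeedSequence([0xD1F, seed]))
        din = d + t_embed_dim

        def init(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "W1": init((din, hidden), din), "b1": np.zeros(hidden),
            "W2": init((hidden, hidden), hidden), "b2": np.zeros(hidden),
            "W3": init((hidden, d), hidden) * 0.01, "b3": np.zeros(d),
            "Wg": np.zeros(t_embed_dim), "bg": np.zeros(1),  # skip gate g(t)
        }

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def _forward(self, x_flat: np.ndarray, t_frac: np.ndarray):
        emb = _time_embedding(t_frac, self.t_embed_dim)
        inp = np.concatenate([x_flat, emb], axis=1)
        p = self.params
        z1 = inp @ p["W1"] + p["b1"]
        a1, s1 = _silu(z1)
        z2 = a1 @ p["W2"] + p["b2"]
        a2, s2 = _silu(z2)
        gate = (emb @ p["Wg"] + p["bg"])[:, None]
        out = a2 @ p["W3"] + p["b3"] + gate * x_flat
        cache = (inp, emb, x_flat, gate, z1, a1, s1, z2, a2, s2)
        return out, cache

    def predict_eps(self, x_t: np.ndarray, t: int) -> np.ndarray:
        single = x_t.ndim == 2
        x = x_t[None] if single else x_t
        flat = x.reshape(len(x), -1)
        tf = np.full(len(x), t / self.T)
        out, _ = self._forward(flat, tf)
        out = out.reshape(x.shape)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("score network produced non-finite output")
        return out[0] if single else out

    def _loss_and_grads(self, x_flat, t_frac, target_flat):
        out, (inp, emb, xf, gate, z1, a1, s1, z2, a2, s2) = self._forward(x_flat, t_frac)
        diff = out - target_flat
        loss = float(np.mean(diff**2))
        p = self.params
        g_out = 2.0 * diff / diff.size
        grads = {}
        g_gate = np.sum(g_out * xf, axis=1)
        grads["Wg"] = emb.T @ g_gate
        grads["bg"] = np.array([g_gate.sum()])
        grads["W3"] = a2.T @ g_out
        grads["b3"] = g_out.sum(axis=0)
        g_a2 = g_out @ p["W3"].T
        g_z2 = g_a2 * (s2 * (1.0 + z2 * (1.0 - s2)))
        grads["W2"] = a1.T @ g_z2
        grads["b2"] = g_z2.sum(axis=0)
        g_a1 = g_z2 @ p["W2"].T
        g_z1 = g_a1 * (s1 * (1.0 + z1 * (1.0 - s1)))
        grads["W1"] = inp.T @ g_z1
        grads["b1"] = g_z1.sum(axis=0)
        return loss, grads


def train_diffusion(
    images,
    schedule: NoiseSchedule,
    model: MLPScoreModel,
    epochs: int = 50,
    seed: int = 0,
    batch_size: int = 32,
    lr: float = 2e-3,
) -> tuple[MLPScoreModel, list]:
    """Epsilon-prediction training: minimize E ||eps - eps_hat(x_t, t)||^2.

    Each step draws a batch, uniform timesteps, and Gaussian noise, forms
    x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps, and takes one Adam step.
    Deterministic given ``seed``; returns the model and the per-epoch mean
    loss trace.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    X = np.stack([np.asarray(im, float).ravel() for im in images])
    if X.min() < -1.0 - 1e-9 or X.max() > 1.0 + 1e-9:
        raise ValueError("training images must be on the normalized [-1, 1] scale")
    rng = np.random.default_rng(np.random.SeedSequence([0x7247, seed]))
    mstate = {k: np.zeros_like(v) for k, v in model.params.items()}
    vstate = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2, eps_adam = 0.9, 0.999, 1e-8
    step = 0
    trace = []
    n = len(X)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            x0 = X[idx]
            t = rng.integers(0, schedule.T, size=len(idx))
            noise = rng.standard_normal(x0.shape)
            ab = schedule.alpha_bar[t][:, None]
            x_t = np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * noise
            loss, grads = model._loss_and_grads(x_t, t / model.T, noise)
            if not np.isfinite(loss):
                raise FloatingPointError(f"NaN training loss at step {step}")
            step += 1
            for k in model.params:
                mstate[k] = b1 * mstate[k] + (1 - b1) * grads[k]
                vstate[k] = b2 * vstate[k] + (1 - b2) * grads[k] ** 2
                mhat = mstate[k] / (1 - b1**step)
                vhat = vstate[k] / (1 - b2**step)
                model.params[k] -= lr * mhat / (np.sqrt(vhat) + eps_adam)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return model, trace


# ---------------------------------------------------------------------------
# sampling


@dataclass(frozen=True)
class GuidanceConfig:
    """Guided-sampler knobs: weight (default 0.1), 50 respaced steps, seed."""

    guidance_weight: float = 0.1
    n_steps: int = 50
    seed: int = 0
    step_schedule: tuple | None = None
    hu_window: tuple[float, float] | None = None
    clip_x0: bool = False

    def __post_init__(self):
        if self.guidance_weight < 0:
            raise ValueError("guidance_weight must be nonnegative")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


def respaced_steps(T: int, n_steps: int) -> np.ndarray:
    """Uniform-stride decreasing timestep subsequence ending at t=0."""
    if n_steps > T:
        raise ValueError("n_steps cannot exceed T")
    return np.unique(np.round(np.linspace(T - 1, 0, n_steps)).astype(int))[::-1]


def guided_sample(
    model,
    schedule: NoiseSchedule,
    obs: Sinogram | None,
    proj: LinearProjector | None,
    cfg: GuidanceConfig,
) -> ReconstructionResult:
    """Ancestral DDPM sampling with measurement guidance on x0_hat.

    At every respaced step: predict eps, form x0_hat, subtract
    guidance_weight * d/dx0_hat MSE(A x0_hat, obs), then take the standard
    DDPM posterior step built from the corrected x0_hat.  With
    ``guidance_weight == 0`` (or ``obs is None``) this is exactly
    unconditional sampling at the same seed.  Deterministic given cfg.seed.
    If ``cfg.hu_window`` is set the returned image is mapped back to HU.
    """
    guided = cfg.guidance_weight > 0 and obs is not None
    if guided:
        if proj is None:
            raise ValueError("guidance requires a projector")
        if obs.values.shape != (proj.nproj, proj.ndet):
            raise ValueError("observation geometry does not match projector")
    n = model.image_size if hasattr(model, "image_size") else proj.image_size
    steps = (np.asarray(cfg.step_schedule, int) if cfg.step_schedule is not None
             else respaced_steps(schedule.T, cfg.n_steps))
    if np.any(np.diff(steps) >= 0):
        raise ValueError("step_schedule must be strictly decreasing")
    rng = np.random.default_rng(np.random.SeedSequence([0x5A3B, cfg.seed]))
    x = rng.standard_normal((n, n))
    m = obs.values.size if guided else 1
    for i, t in enumerate(steps):
        eps_hat = model.predict_eps(x, int(t))
        x0_hat = predict_x0(x, eps_hat, int(t), schedule)
        if cfg.clip_x0:
            # keep the clean-image estimate on the data scale; stabilizes
            # sampling from imperfect score networks (no-op for a well
            # calibrated predictor of [-1, 1] images)
            x0_hat = np.clip(x0_hat, -1.0, 1.0)
        if guided:
            residual = proj.forward(x0_hat).values - obs.values
            grad = (2.0 / m) * proj.adjoint(residual)
            x0_hat = x0_hat - cfg.guidance_weight * grad
        if not np.all(np.isfinite(x0_hat)):
            raise FloatingPointError(f"non-finite iterate at sampling step {i} (t={t})")
        ab_t = schedule.alpha_bar[t]
        if i + 1 < len(steps):
            t_prev = steps[i + 1]
            ab_prev = schedule.alpha_bar[t_prev]
            # sigma_t^2 = beta_t (the upper of the two standard DDPM choices;
            # exact for unit-variance data and well calibrated on the
            # analytic Gaussian testbed, unlike the posterior lower bound)
            beta_eff = 1.0 - ab_t / ab_prev
            var = beta_eff
            mean = (
                np.sqrt(ab_prev) * beta_eff / (1.0 - ab_t) * x0_hat
                + np.sqrt(ab_t / ab_prev) * (1.0 - ab_prev) / (1.0 - ab_t) * x
            )
            x = mean + np.sqrt(max(var, 0.0)) * rng.standard_normal((n, n))
        else:
            x = x0_hat
    if cfg.hu_window is not None:
        from .phantoms import model_scale_to_hu
        x = model_scale_to_hu(np.clip(x, -1.0, 1.0), cfg.hu_window)
    nproj = proj.nproj if proj is not None else 0
    return ReconstructionResult(x, Method.DIFFUSION.value, nproj,
                                cfg.guidance_weight, [], True)


def unconditional_sample(model, schedule: NoiseSchedule, cfg: GuidanceConfig) -> np.ndarray:
    """Plain ancestral sampling (guidance off); same seed path as guided_sample."""
    off = GuidanceConfig(0.0, cfg.n_steps, cfg.seed, cfg.step_schedule, None, cfg.clip_x0)
    return guided_sample(model, schedule, None, None, off).image


def gaussian_posterior_mean(mean: np.ndarray, var: float, proj: LinearProjector,
                            obs: Sinogram) -> np.ndarray:
    """Closed-form posterior mean for x ~ N(mean, var I) given exact b = Ax.

    Dense linear algebra: mean + var A^T (var A A^T)^+ (b - A mean); the
    pseudo-inverse handles rank deficiency at few angles.
    """
    A = proj.matrix.toarray()
    mu = np.asarray(mean, float).ravel()
    b = obs.values.ravel()
    gram = var * (A @ A.T)
    corr = var * A.T @ np.linalg.pinv(gram, rcond=1e-10) @ (b - A @ mu)
    return (mu + corr).reshape(proj.image_size, proj.image_size)
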