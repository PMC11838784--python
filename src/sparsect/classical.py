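"""Classical-prior reconstructions: Tikhonov (L2) and total-variation (L1).

Both solve ``min_x ||Ax - b||^2 + lam * R(x)`` with A the parallel-beam
projector.  Tikhonov (R = ||x||^2, or optionally ||grad x||^2) is solved by
conjugate gradients on the normal equations, so the objective decreases
monotonically over the Krylov iterations.  TV (R = isotropic total variation,
forward differences, reflective boundary) is solved by monotone FISTA with the
TV proximal operator computed by Chambolle's dual projection algorithm; the
monotone variant guarantees a non-increasing objective trace while keeping
FISTA's fast convergence.

Solvers are scale-agnostic: they reconstruct on whatever intensity scale the
sinogram was measured on (the experiment pipeline runs them on the normalized
[-1, 1] scale the diffusion model uses, so a given ``lam`` means the same
thing for every prior, then maps results back to HU).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .projection import LinearProjector, Sinogram


class Method(str, Enum):
    L1_TV = "L1_TV"
    L2_TIKHONOV = "L2_TIKHONOV"
    DIFFUSION = "DIFFUSION"


@dataclass(frozen=True)
class ClassicalConfig:
    """Solver configuration; defaults lam=10, n_iters=1000."""

    method: Method = Method.L1_TV
    lam: float = 10.0
    n_iters: int = 1000
    step_size: float | str = "auto"
    nonneg: bool = False
    l2_penalty: str = "identity"  # or "gradient" for a smoothness penalty
    tv_inner_iters: int = 30
    tol: float = 1e-6

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.n_iters < 1:
            raise ValueError("n_iters must be positive")


@dataclass
class ReconstructionResult:
    image: np.ndarray
    method: str
    nproj: int
    lam: float
    objective_trace: list = field(default_factory=list)
    converged: bool = True


def _grad(x):
    """Forward differences with reflective (replicate-edge) boundary."""
    gx = np.diff(x, axis=1, append=x[:, -1:])
    gy = np.diff(x, axis=0, append=x[-1:, :])
    return gx, gy


def _div(gx, gy):
    """Negative adjoint of ``_grad`` (discrete divergence)."""
    dx = np.empty_like(gx)
    dx[:, 0] = gx[:, 0]
    dx[:, 1:-1] = gx[:, 1:-1] - gx[:, :-2]
    dx[:, -1] = -gx[:, -2]
    dy = np.empty_like(gy)
    dy[0, :] = gy[0, :]
    dy[1:-1, :] = gy[1:-1, :] - gy[:-2, :]
    dy[-1, :] = -gy[-2, :]
    return dx + dy


def total_variation(x: np.ndarray) -> float:
    """Isotropic TV: sum over pixels of the gradient magnitude."""
    gx, gy = _grad(x)
    return float(np.sum(np.sqrt(gx**2 + gy**2)))


def tv_prox(z: np.ndarray, weight: float, n_iters: int = 30) -> np.ndarray:
    """Chambolle dual projection for argmin_u  0.5||u - z||^2 + weight*TV(u)."""
    if weight <= 0:
        return z.copy()
    px = np.zeros_like(z)
    py = np.zeros_like(z)
    tau = 0.125  # convergence bound for the 2D gradient operator (||grad||^2 <= 8)
    for _ in range(n_iters):
        u = z - weight * _div(px, py)
        gx, gy = _grad(u)
        norm = np.sqrt(gx**2 + gy**2)
        denom = 1.0 + (tau / weight) * norm
        px = (px - (tau / weight) * gx) / denom
        py = (py - (tau / weight) * gy) / denom
    return z - weight * _div(px, py)


def operator_norm_sq(proj: LinearProjector, n_iters: int = 100) -> float:
    """Power-method estimate of ||A||^2 (largest eigenvalue of A^T A)."""
    x = np.ones((proj.image_size, proj.image_size))
    lam = 1.0
    for _ in range(n_iters):
        y = proj.adjoint(proj.forward(x).values)
        lam = float(np.linalg.norm(y))
        if lam == 0:
            return 0.0
        x = y / lam
    return lam


def _objective_l2(proj, x, b, lam, penalty):
    r = proj.forward(x).values - b
    if penalty == "gradient":
        gx, gy = _grad(x)
        pen = np.sum(gx**2 + gy**2)
    else:
        pen = np.sum(x**2)
    return float(np.sum(r**2) + lam * pen)


def reconstruct_tikhonov(
    sino: Sinogram, proj: LinearProjector, cfg: ClassicalConfig | None = None
) -> ReconstructionResult:
    """CG on the normal equations (A^T A + lam*P) x = A^T b.

    ``P`` is the identity by default or the gradient Laplacian when
    ``cfg.l2_penalty == "gradient"``.  Stops when the relative residual of the
    normal equations falls below ``cfg.tol`` or after ``cfg.n_iters``
    iterations; non-convergence is reported via the ``converged`` flag.
    """
    cfg = cfg or ClassicalConfig(method=Method.L2_TIKHONOV)
    if cfg.method != Method.L2_TIKHONOV:
        raise ValueError("cfg.method must be L2_TIKHONOV")
    n = proj.image_size
    b = sino.values
    atb = proj.adjoint(b).ravel()

    def normal_op(v):
        img = v.reshape(n, n)
        out = proj.adjoint(proj.forward(img).values)
        if cfg.lam > 0:
            if cfg.l2_penalty == "gradient":
                gx, gy = _grad(img)
                out = out - cfg.lam * _div(gx, gy)  # grad^T grad = -div o grad
            else:
                out = out + cfg.lam * img
        return out.ravel()

    # hand-rolled CG so we can log the true objective each iteration
    x = np.zeros(n * n)
    r = atb - normal_op(x)
    p = r.copy()
    rs = float(r @ r)
    b_norm = float(np.linalg.norm(atb)) or 1.0
    trace = [_objective_l2(proj, x.reshape(n, n), b, cfg.lam, cfg.l2_penalty)]
    converged = rs**0.5 / b_norm <= cfg.tol
    for _ in range(cfg.n_iters):
        if converged:
            break
        ap = normal_op(p)
        denom = float(p @ ap)
        if denom <= 0:
            break
        alpha = rs / denom
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = float(r @ r)
        trace.append(_objective_l2(proj, x.reshape(n, n), b, cfg.lam, cfg.l2_penalty))
        if rs_new**0.5 / b_norm <= cfg.tol:
            converged = True
        p = r + (rs_new / rs) * p
        rs = rs_new
    img = x.reshape(n, n)
    if cfg.nonneg:
        img = np.maximum(img, 0.0)
    return ReconstructionResult(
        img, Method.L2_TIKHONOV.value, proj.nproj, cfg.lam, trace, converged
    )


def reconstruct_tv(
    sino: Sinogram, proj: LinearProjector, cfg: ClassicalConfig | None = None
) -> ReconstructionResult:
    """Monotone FISTA for ||Ax-b||^2 + lam*TV(x), exactly cfg.n_iters iterations."""
    cfg = cfg or ClassicalConfig(method=Method.L1_TV)
    if cfg.method != Method.L1_TV:
        raise ValueError("cfg.method must be L1_TV")
    n = proj.image_size
    b = sino.values
    if cfg.step_size == "auto":
        L = 2.0 * operator_norm_sq(proj)
        alpha = 1.0 / L if L > 0 else 1.0
    else:
        alpha = float(cfg.step_size)

    def objective(x):
        r = proj.forward(x).values - b
        return float(np.sum(r**2) + cfg.lam * total_variation(x))

    x = np.zeros((n, n))
    y = x.copy()
    t = 1.0
    fx = objective(x)
    trace = [fx]
    for k in range(cfg.n_iters):
        grad = 2.0 * proj.adjoint(proj.forward(y).values - b)
        z = tv_prox(y - alpha * grad, alpha * cfg.lam, cfg.tv_inner_iters)
        if cfg.nonneg:
            z = np.maximum(z, 0.0)
        if not np.all(np.isfinite(z)):
            raise FloatingPointError(f"non-finite TV iterate at iteration {k}")
        fz = objective(z)
        # monotone FISTA: the accepted iterate never increases the objective
        if fz <= fx:
            x_new, f_new = z, fz
        else:
            x_new, f_new = x, fx
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = x_new + (t / t_new) * (z - x_new) + ((t - 1.0) / t_new) * (x_new - x)
        x, fx, t = x_new, f_new, t_new
        trace.append(fx)
    return ReconstructionResult(x, Method.L1_TV.value, proj.nproj, cfg.lam, trace, True)
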