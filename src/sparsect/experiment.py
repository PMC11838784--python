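"""End-to-end sweeps: (slice x method x nproj) reconstruction and scoring.

One run generates a held-out phantom set, simulates noiseless sinograms on
the normalized [-1, 1] scale per projection count, reconstructs with every
requested prior (TV, Tikhonov, guided diffusion), scores each reconstruction
in HU, and finally summarizes metric curves and the diffusion-vs-classical
dominance intervals.  Everything is a pure function of (config, seed): the
diffusion training set and the evaluation set come from disjoint seed
streams, sinograms are noiseless by default (optional Gaussian noise), and
one trained checkpoint is reused across all projection counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .phantoms import (PhantomSpec, generate_dataset, hu_to_model_scale,
                       model_scale_to_hu, tiny_spec)
from .projection import LinearProjector, Sinogram, make_angle_set
from .classical import ClassicalConfig, Method, reconstruct_tikhonov, reconstruct_tv
from .diffusion import (GuidanceConfig, MLPScoreModel, build_cosine_schedule,
                        guided_sample, train_diffusion)
from .metrics import evaluate_slice
from .bounds import (BoundConfig, MetricCurve, compute_bounds, find_corner,
                     summarize_curve)

log = logging.getLogger("sparsect")

METRIC_COLUMNS = ["slice_id", "method", "nproj", "psnr_db", "ssim",
                  "fat_content_acc", "fat_dice"]
METRIC_NAMES = ["psnr_db", "ssim", "fat_content_acc", "fat_dice"]

#: default sweep covering the landmark projection counts {7, 15, 25, 40, 60}
DEFAULT_NPROJ_GRID = (2, 5, 7, 10, 15, 25, 40, 60, 90, 180, 360)

# seed-stream labels: training and evaluation phantoms never share seeds
_TRAIN_STREAM, _EVAL_STREAM, _SAMPLER_STREAM = 101, 202, 303


@dataclass
class ExperimentConfig:
    nproj_grid: tuple = DEFAULT_NPROJ_GRID
    methods: tuple = (Method.L1_TV, Method.L2_TIKHONOV, Method.DIFFUSION)
    n_slices: int = 10
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=lambda: tiny_spec(32))
    hu_window: tuple = (-1000.0, 1000.0)
    lam_tv: float = 10.0
    lam_tikhonov: float = 10.0
    guidance_weight: float = 0.1
    n_iters: int = 1000
    diffusion_steps: int = 50
    schedule_T: int = 1000
    n_train_slices: int = 200
    train_epochs: int = 300
    sinogram_noise_sd: float = 0.0
    tau_p: float = 0.05
    output_dir: str | None = None

    def __post_init__(self):
        grid = tuple(sorted(int(k) for k in self.nproj_grid))
        if grid[0] < 1 or grid[-1] > 360:
            raise ValueError("nproj values must lie in [1, 360]")
        self.nproj_grid = grid
        self.methods = tuple(Method(m) for m in self.methods)
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


def _stream_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([int(seed), stream]).generate_state(1)[0]) % (2**31)


def make_projectors(image_size: int, nproj_grid, spacing_mm: float = 1.0) -> dict:
    return {k: LinearProjector(image_size, make_angle_set(k), spacing_mm=spacing_mm)
            for k in nproj_grid}


def train_prior(cfg: ExperimentConfig) -> tuple[MLPScoreModel, list]:
    """Train the diffusion prior on its own seed stream of phantoms."""
    t0 = time.perf_counter()
    train_set = generate_dataset(cfg.n_train_slices, cfg.phantom,
                                 _stream_seed(cfg.seed, _TRAIN_STREAM))
    images = [hu_to_model_scale(img, cfg.hu_window) for img, _ in train_set]
    schedule = build_cosine_schedule(cfg.schedule_T)
    model = MLPScoreModel(cfg.phantom.size, T=cfg.schedule_T,
                          seed=_stream_seed(cfg.seed, _TRAIN_STREAM))
    model, trace = train_diffusion(images, schedule, model,
                                   epochs=cfg.train_epochs,
                                   seed=_stream_seed(cfg.seed, _TRAIN_STREAM))
    log.info("stage=train n=%d epochs=%d loss %.4f -> %.4f wall=%.1fs",
             len(images), cfg.train_epochs, trace[0], trace[-1],
             time.perf_counter() - t0)
    return model, trace


def _reconstruct(method: Method, sino: Sinogram, proj: LinearProjector,
                 cfg: ExperimentConfig, model, schedule, sample_seed: int):
    if method == Method.L1_TV:
        c = ClassicalConfig(method=Method.L1_TV, lam=cfg.lam_tv, n_iters=cfg.n_iters)
        return reconstruct_tv(sino, proj, c).image
    if method == Method.L2_TIKHONOV:
        c = ClassicalConfig(method=Method.L2_TIKHONOV, lam=cfg.lam_tikhonov,
                            n_iters=cfg.n_iters)
        return reconstruct_tikhonov(sino, proj, c).image
    gcfg = GuidanceConfig(cfg.guidance_weight, cfg.diffusion_steps,
                          seed=sample_seed, clip_x0=True)
    return guided_sample(model, schedule, sino, proj, gcfg).image


def run_experiment(cfg: ExperimentConfig, model: MLPScoreModel | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full sweep; returns (metrics table, bounds table) and writes CSVs.

    ``model`` may carry a pre-trained diffusion prior (reused across all
    nproj); if absent and DIFFUSION is requested, training runs first.
    """
    schedule = build_cosine_schedule(cfg.schedule_T)
    if Method.DIFFUSION in cfg.methods and model is None:
        model, _ = train_prior(cfg)
    if Method.DIFFUSION in cfg.methods and model.image_size != cfg.phantom.size:
        raise ValueError("diffusion checkpoint size does not match phantom size")

    eval_set = generate_dataset(cfg.n_slices, cfg.phantom,
                                _stream_seed(cfg.seed, _EVAL_STREAM))
    projectors = make_projectors(cfg.phantom.size, cfg.nproj_grid)
    noise_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))

    rows = []
    for s_idx, (img, _mask) in enumerate(eval_set):
        x_norm = hu_to_model_scale(img, cfg.hu_window)
        for k in cfg.nproj_grid:
            proj = projectors[k]
            sino = proj.forward(x_norm)
            if cfg.sinogram_noise_sd > 0:
                noisy = sino.values + noise_rng.normal(
                    0.0, cfg.sinogram_noise_sd, sino.values.shape)
                sino = Sinogram(noisy, sino.angles, sino.det_spacing)
            for method in cfg.methods:
                t0 = time.perf_counter()
                sample_seed = _stream_seed(cfg.seed, _SAMPLER_STREAM) + s_idx
                recon_norm = _reconstruct(method, sino, proj, cfg, model,
                                          schedule, sample_seed)
                recon_hu = model_scale_to_hu(np.clip(recon_norm, -1, 1), cfg.hu_window)
                rec = evaluate_slice(img, recon_hu, slice_id=f"slice{s_idx:03d}",
                                     method=method.value, nproj=k)
                rows.append(dataclasses.asdict(rec))
                log.info("stage=recon slice=%d nproj=%d method=%s wall=%.2fs",
                         s_idx, k, method.value, time.perf_counter() - t0)
    metrics_df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    bounds_df = compute_bounds_table(metrics_df, tau_p=cfg.tau_p)

    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics_df.to_csv(out / "metrics.csv", index=False)
        bounds_df.to_csv(out / "bounds.csv", index=False)
        if cfg.n_slices >= 2:
            for metric in METRIC_NAMES:
                summary_frames = []
                for method in metrics_df["method"].unique():
                    curve = curve_from_table(metrics_df, metric, method)
                    sdf = pd.DataFrame([dataclasses.asdict(r) for r in summarize_curve(curve)])
                    sdf.insert(0, "method", method)
                    summary_frames.append(sdf)
                pd.concat(summary_frames).to_csv(out / f"summary_{metric}.csv", index=False)
        (out / "config.json").write_text(_config_json(cfg))
    return metrics_df, bounds_df


def _config_json(cfg: ExperimentConfig) -> str:
    d = asdict(cfg)
    d["methods"] = [m.value for m in cfg.methods]
    return json.dumps(d, indent=2, default=str)


def curve_from_table(metrics_df: pd.DataFrame, metric: str, method: str) -> MetricCurve:
    sub = metrics_df[metrics_df["method"] == method]
    samples = {int(k): g[metric].to_numpy() for k, g in sub.groupby("nproj")}
    return MetricCurve(metric, method, samples, direction="increasing")


def compute_bounds_table(metrics_df: pd.DataFrame, tau_p: float = 0.05,
                         candidate: str = Method.DIFFUSION.value) -> pd.DataFrame:
    """Corner LB + Mann-Whitney UB of the candidate against every baseline."""
    methods = list(metrics_df["method"].unique())
    baselines = [m for m in methods if m != candidate]
    too_few = metrics_df.groupby(["method", "nproj"]).size().min() < 2
    if candidate not in methods or not baselines or too_few:
        return pd.DataFrame(columns=["metric", "baseline", "LB", "UB", "p_at_UB"])
    out = []
    for metric in METRIC_NAMES:
        cand = curve_from_table(metrics_df, metric, candidate)
        if len(cand.nproj_grid) >= 3:
            corner = find_corner(summarize_curve(cand))
            lb = corner.nproj
        else:
            lb = None
        for base in baselines:
            bi = compute_bounds(cand, curve_from_table(metrics_df, metric, base),
                                BoundConfig(tau_p=tau_p))
            out.append({
                "metric": metric, "baseline": base, "LB": lb, "UB": bi.UB,
                "p_at_UB": bi.p_values.get(bi.UB) if bi.UB is not None else None,
            })
    return pd.DataFrame(out, columns=["metric", "baseline", "LB", "UB", "p_at_UB"])


def grid_search_lambda(method: Method, lambda_grid, dataset, seed: int = 0,
                       nproj: int = 360, n_iters: int = 1000,
                       hu_window: tuple = (-1000.0, 1000.0),
                       model=None, schedule=None,
                       diffusion_steps: int = 50) -> tuple[float, pd.DataFrame]:
    """Pick the regularization/guidance weight with lowest image MSE.

    Every candidate value reconstructs every slice at ``nproj`` projections
    (360 by default, i.e. the fully-sampled setting); the winner minimizes
    the mean image-domain MSE against ground truth, ties toward the smaller
    value.  Returns (chosen value, full MSE table).
    """
    method = Method(method)
    lambda_grid = list(lambda_grid)
    if not lambda_grid or not dataset:
        raise ValueError("need a nonempty lambda grid and dataset")
    size = dataset[0][0].size
    proj = LinearProjector(size, make_angle_set(nproj))
    records = []
    for lam in lambda_grid:
        mses, failed = [], False
        for s_idx, (img, _) in enumerate(dataset):
            x_norm = hu_to_model_scale(img, hu_window)
            sino = proj.forward(x_norm)
            try:
                if method == Method.L1_TV:
                    c = ClassicalConfig(method=method, lam=lam, n_iters=n_iters)
                    rec = reconstruct_tv(sino, proj, c).image
                elif method == Method.L2_TIKHONOV:
                    c = ClassicalConfig(method=method, lam=lam, n_iters=n_iters)
                    rec = reconstruct_tikhonov(sino, proj, c).image
                else:
                    gcfg = GuidanceConfig(lam, diffusion_steps, seed=seed + s_idx)
                    rec = guided_sample(model, schedule, sino, proj, gcfg).image
            except FloatingPointError as err:
                log.warning("lambda=%g excluded: %s", lam, err)
                failed = True
                break
            mses.append(float(np.mean((rec - x_norm) ** 2)))
        records.append({"lam": lam,
                        "mse": float(np.mean(mses)) if not failed else np.inf})
    table = pd.DataFrame(records)
    best = table.loc[table["mse"].idxmin()]  # idxmin takes the first minimum
    return float(best["lam"]), table


def plot_curves(metric_csv, out_dir) -> list:
    """Median + IQR5,95 band per method vs nproj, one PNG per metric."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = pd.read_csv(metric_csv)
    if df.empty:
        raise ValueError("metric table is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for metric in METRIC_NAMES:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for method in sorted(df["method"].unique()):
            sub = df[df["method"] == method].groupby("nproj")[metric]
            ks = sorted(sub.groups)
            med = sub.median().loc[ks]
            q05 = sub.quantile(0.05).loc[ks]
            q95 = sub.quantile(0.95).loc[ks]
            ax.plot(ks, med, marker="o", label=method)
            ax.fill_between(ks, q05, q95, alpha=0.25)
        ax.set_xscale("log")
        ax.set_xlabel("number of projections")
        ax.set_ylabel(metric)
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out / f"curve_{metric}.png"
        fig.savefig(path, dpi=120, metadata={"Software": None})
        plt.close(fig)
        paths.append(path)
    return paths
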