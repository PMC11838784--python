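import numpy as np
import pytest

from sparsect.diffusion import build_cosine_schedule
from sparsect.experiment import ExperimentConfig, train_prior
from sparsect.phantoms import tiny_spec


@pytest.fixture(scope="session")
def schedule1000():
    return build_cosine_schedule(1000)


@pytest.fixture(scope="session")
def tiny_experiment_cfg():
    """Desk-scale study conditions: 32^2 phantoms, 200 training slices,
    10 held-out evaluation slices, nproj sweep {5, 10, 45, 180}."""
    return ExperimentConfig(
        nproj_grid=(5, 10, 45, 180),
        n_slices=10,
        seed=7,
        phantom=tiny_spec(32),
        n_train_slices=200,
        train_epochs=300,
        n_iters=1000,
    )


@pytest.fixture(scope="session")
def trained_prior(tiny_experiment_cfg):
    """One diffusion checkpoint, reused by every test that needs it."""
    model, trace = train_prior(tiny_experiment_cfg)
    return model, trace


def disk_phantom(n: int = 64, r: float = 10.0, supersample: int = 8) -> np.ndarray:
    """Area-antialiased centered unit disk (shared projection fixture)."""
    half = (n - 1) / 2
    yy, xx = np.mgrid[0:n, 0:n]
    acc = np.zeros((n, n))
    for dy in range(supersample):
        for dx in range(supersample):
            y = yy + (dy + 0.5) / supersample - 0.5 - half
            x = xx + (dx + 0.5) / supersample - 0.5 - half
            acc += (x * x + y * y) <= r * r
    return acc / supersample**2
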