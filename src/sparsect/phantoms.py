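"""Seeded 2D chest-like CT phantoms with Hounsfield-unit compartments.

The generator stands in for clinical axial chest-wall slices: an elliptical
body with a thin soft-tissue rind, a subcutaneous fat ring, two lungs, a
spine/rib-like set of bone inserts, and soft tissue elsewhere.  Compartment
means are standard CT values (air -1000 HU, lung -800, fat -100, soft +40,
bone +400) so the fat compartment sits centered in the -150..-50 HU window
used for downstream fat quantification.  Anatomy (body axes, fat thickness,
lung placement) is randomized per seed; output is piecewise-constant HU plus
per-pixel jitter, softened by a sub-pixel Gaussian blur to mimic
partial-volume edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, label as cc_label

HU_MIN = -1024.0
HU_MAX = 3071.0

#: standard compartment attenuation values (HU)
DEFAULT_HU_MEANS = {
    "air": -1000.0,
    "lung": -800.0,
    "fat": -100.0,
    "soft": 40.0,
    "bone": 400.0,
}

# admissible windows per compartment; generation rejects means outside these
_COMPARTMENT_WINDOWS = {
    "air": (HU_MIN, -900.0),
    "lung": (HU_MIN, -500.0),
    "fat": (-150.0, -50.0),
    "soft": (-50.0, 150.0),
    "bone": (150.0, HU_MAX),
}

_LABELS = ("air", "lung", "fat", "soft", "bone")


@dataclass(frozen=True)
class ImageHU:
    """A square 2D slice of attenuation values in Hounsfield units."""

    pixels: np.ndarray
    spacing_mm: float = 1.0

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"expected a square 2D slice, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("HU image contains non-finite values")
        if px.min() < HU_MIN or px.max() > HU_MAX:
            raise ValueError(
                f"HU values outside [{HU_MIN}, {HU_MAX}]: "
                f"range [{px.min():.1f}, {px.max():.1f}]"
            )
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class FatLabelMask:
    """Ground-truth boolean mask of the fat compartment."""

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2D")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one randomized chest phantom.

    ``body_axes`` are semi-axes as fractions of the half-image; jitter is the
    per-pixel HU noise s.d.; ``smoothness_sigma`` (pixels) softens edges.
    """

    size: int = 128
    seed: int = 0
    body_axes: tuple[float, float] = (0.88, 0.72)
    fat_ring_thickness: float = 0.10  # fraction of the body minor semi-axis
    n_lungs: int = 2
    n_bone: int = 5
    hu_means: dict = field(default_factory=lambda: dict(DEFAULT_HU_MEANS))
    hu_jitter: float = 10.0
    smoothness_sigma: float = 0.15

    def __post_init__(self):
        if self.size < 8:
            raise ValueError("size must be >= 8")
        if self.hu_jitter < 0 or self.smoothness_sigma < 0:
            raise ValueError("hu_jitter and smoothness_sigma must be nonnegative")
        for name, mean in self.hu_means.items():
            lo, hi = _COMPARTMENT_WINDOWS.get(name, (HU_MIN, HU_MAX))
            if not lo <= mean <= hi:
                raise ValueError(
                    f"HU mean for compartment '{name}' is {mean}, "
                    f"outside its admissible window [{lo}, {hi}]"
                )


def tiny_spec(size: int = 32, seed: int = 0, **kw) -> PhantomSpec:
    """Small preset (32 or 64 pixels) for fast experiments and tests."""
    return PhantomSpec(size=size, seed=seed, n_bone=3, **kw)


def _ellipse(xx, yy, cx, cy, ax_, ay):
    return ((xx - cx) / ax_) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def generate_chest_phantom(spec: PhantomSpec) -> tuple[ImageHU, FatLabelMask]:
    """Generate one seeded phantom and its ground-truth fat mask.

    Deterministic given ``spec`` (including its seed).  The body is a single
    connected elliptical region; the fat ring lies just inside a thin
    soft-tissue rind so at least 99% of fat-labeled pixels read inside the
    -150..-50 HU window after jitter and sub-pixel smoothing.
    """
    rng = np.random.default_rng(np.random.SeedSequence([0x5FA7, spec.seed]))
    n = spec.size
    half = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    x = (xx - half) / half
    y = (yy - half) / half

    # per-seed anatomy jitter
    ax_ = spec.body_axes[0] * rng.uniform(0.92, 1.05)
    ay = spec.body_axes[1] * rng.uniform(0.92, 1.05)
    ax_, ay = min(ax_, 0.98), min(ay, 0.98)
    thick = spec.fat_ring_thickness * rng.uniform(0.8, 1.2)

    labels = np.zeros((n, n), dtype=np.int8)  # 0=air
    body = _ellipse(x, y, 0.0, 0.0, ax_, ay)
    rind = 0.035  # soft-tissue skin thickness, fraction of semi-axis
    fat_outer = _ellipse(x, y, 0.0, 0.0, ax_ * (1 - rind), ay * (1 - rind))
    fat_inner = _ellipse(
        x, y, 0.0, 0.0, ax_ * (1 - rind - thick), ay * (1 - rind - thick)
    )
    labels[body] = _LABELS.index("soft")
    fat_ring = fat_outer & ~fat_inner
    labels[fat_ring] = _LABELS.index("fat")

    # lungs: ellipses inside the fat ring's interior
    for i in range(spec.n_lungs):
        side = -1 if i % 2 == 0 else 1
        cx = side * rng.uniform(0.28, 0.42) * ax_
        cy = rng.uniform(-0.15, 0.05) * ay
        lx = rng.uniform(0.18, 0.26) * ax_
        ly = rng.uniform(0.26, 0.38) * ay
        lung = _ellipse(x, y, cx, cy, lx, ly) & fat_inner
        labels[lung] = _LABELS.index("lung")

    # bone: spine blob at the back plus rib-like dots along the inner ring
    if spec.n_bone >= 1:
        spine = _ellipse(x, y, 0.0, 0.62 * ay, 0.12 * ax_, 0.10 * ay) & fat_inner
        labels[spine] = _LABELS.index("bone")
    for i in range(max(0, spec.n_bone - 1)):
        theta = rng.uniform(0, 2 * np.pi)
        r = 1 - rind - thick - 0.08
        cx, cy = r * ax_ * np.cos(theta), r * ay * np.sin(theta)
        rib = _ellipse(x, y, cx, cy, 0.04, 0.04) & fat_inner
        labels[rib] = _LABELS.index("bone")

    hu = np.empty((n, n), dtype=float)
    for idx, name in enumerate(_LABELS):
        hu[labels == idx] = spec.hu_means[name]
    if spec.hu_jitter > 0:
        hu += rng.normal(0.0, spec.hu_jitter, size=hu.shape)
    if spec.smoothness_sigma > 0:
        hu = gaussian_filter(hu, spec.smoothness_sigma, mode="nearest")
    hu = np.clip(hu, HU_MIN, HU_MAX)

    img = ImageHU(hu, spacing_mm=1.0)
    mask = FatLabelMask(labels == _LABELS.index("fat"))
    return img, mask


def body_is_connected(img: ImageHU, air_threshold: float = -900.0) -> bool:
    """True if the non-air region forms a single connected component."""
    _, ncomp = cc_label(img.pixels > air_threshold)
    return ncomp == 1


def dataset_member_seed(base_seed: int, index: int) -> int:
    """Stable child seed for dataset member ``index``.

    Derived from ``SeedSequence([base_seed, index])`` so the mapping is
    documented, collision-resistant, and identical across runs and platforms.
    """
    return int(np.random.SeedSequence([int(base_seed), int(index)]).generate_state(1)[0])


def generate_dataset(
    n_slices: int, base_spec: PhantomSpec, seed: int
) -> list[tuple[ImageHU, FatLabelMask]]:
    """Generate ``n_slices`` distinct phantoms from one base recipe.

    Member ``i`` uses :func:`dataset_member_seed`, so the sequence is fully
    reproducible from ``(base_spec, seed)`` and members differ pairwise.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    out = []
    for i in range(n_slices):
        spec_i = replace(base_spec, seed=dataset_member_seed(seed, i))
        out.append(generate_chest_phantom(spec_i))
    return out


def hu_to_model_scale(img, window: tuple[float, float] = (-1000.0, 1000.0)) -> np.ndarray:
    """Affine map of HU into [-1, 1], clipping to ``window`` first.

    Accepts an :class:`ImageHU` or a plain array.  Exact inverse of
    :func:`model_scale_to_hu` for in-window values.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"degenerate window {window}")
    px = img.pixels if isinstance(img, ImageHU) else np.asarray(img, dtype=float)
    clipped = np.clip(px, lo, hi)
    return 2.0 * (clipped - lo) / (hi - lo) - 1.0


def model_scale_to_hu(arr: np.ndarray, window: tuple[float, float] = (-1000.0, 1000.0)) -> np.ndarray:
    """Inverse of :func:`hu_to_model_scale` on the normalized [-1, 1] scale."""
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"degenerate window {window}")
    return (np.asarray(arr, dtype=float) + 1.0) * (hi - lo) / 2.0 + lo
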