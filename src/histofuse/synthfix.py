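"""Synthetic fixtures: histology-like images and backbone feature triplets.

Nothing downstream needs a real dataset: ``make_image`` draws a two-class
blob-texture tile (pale stroma background, dark elliptical nuclei with
optionally irregular boundaries — the adenocarcinoma class packs more and
rougher nuclei), and ``make_feature_triplet`` draws three correlated
feature matrices that emulate the statistics of deep global-pool
features: non-negative, strongly right-skewed (lognormal-shaped, the
regime produced by ReLU activations), with a planted class shift on a
subset of informative columns shared across the three "backbones".

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SynthImageSpec",
    "SynthFeatureSpec",
    "make_image",
    "image_spec_for_class",
    "make_feature_triplet",
    "benchmark_fitness",
]


@dataclass
class SynthImageSpec:
    """Parameters of one synthetic tile.

    Defaults describe a benign 224x224 tile at the pipeline's working
    resolution: 8 nuclei of radius 8-16 px, hematoxylin-dark nuclei
    (mean 80) on pale stroma (mean 200), acquisition noise sd 8.
    ``irregularity`` in [0, 1] scales a sinusoidal boundary perturbation.
    """

    size: tuple[int, int] = (224, 224)
    n_nuclei: int = 8
    radius_range: tuple[float, float] = (8.0, 16.0)
    background_mean: float = 200.0
    nucleus_mean: float = 80.0
    noise_sd: float = 8.0
    irregularity: float = 0.15
    label: int = 0  # 0 = benign, 1 = adenocarcinoma
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0.0 <= self.irregularity <= 1.0:
            raise ValueError("irregularity must be in [0, 1]")
        if self.radius_range[1] * 2 >= min(self.size):
            raise ValueError("nuclei do not fit within the image")


def image_spec_for_class(label: int, seed: int = 0,
                         size: tuple[int, int] = (224, 224),
                         noise_sd: float = 8.0) -> SynthImageSpec:
    """Class presets mimicking nuclear morphometry rather than stain load.

    Both classes carry the same expected stained area (~20% of the
    tile), so global intensity statistics barely separate them: benign
    tiles have few, large, round nuclei; adenocarcinoma tiles twice as
    many smaller nuclei with rough, irregular boundaries.  Radii scale
    with the tile so the composition is resolution-invariant.
    """
    s = float(min(size))
    if label == 0:
        return SynthImageSpec(size=size, n_nuclei=5,
                              radius_range=(0.090 * s, 0.140 * s),
                              irregularity=0.15,
                              noise_sd=noise_sd, label=0, seed=seed)
    return SynthImageSpec(size=size, n_nuclei=10,
                          radius_range=(0.065 * s, 0.100 * s),
                          irregularity=0.5,
                          noise_sd=noise_sd, label=1, seed=seed)


def make_image(spec: SynthImageSpec):
    """Render a tile and its ground-truth nucleus mask.

    Nuclei are ellipses with a sinusoidal boundary perturbation of
    relative amplitude ``0.3 * irregularity``; centres are rejection-
    sampled to avoid heavy overlap, and an overcrowded spec (no room
    after 200 attempts per nucleus) raises.  Returns (image, mask) with
    the image a float array in [0, 255].
    """
    H, W = spec.size
    rng = np.random.default_rng(spec.seed)
    img = np.full((H, W), spec.background_mean, dtype=float)
    # low-frequency stromal texture
    ty = np.sin(2 * np.pi * np.arange(H)[:, None] / max(16, H // 4) + rng.uniform(0, 6.28))
    tx = np.cos(2 * np.pi * np.arange(W)[None, :] / max(16, W // 4) + rng.uniform(0, 6.28))
    img += 5.0 * ty * tx
    mask = np.zeros((H, W), dtype=bool)
    ys, xs = np.mgrid[0:H, 0:W]
    centers: list[tuple[float, float, float]] = []
    r_lo, r_hi = spec.radius_range
    for _ in range(spec.n_nuclei):
        placed = False
        for _attempt in range(200):
            r1 = rng.uniform(r_lo, r_hi)
            r2 = rng.uniform(r_lo, r_hi)
            margin = max(r1, r2) * (1.0 + 0.3 * spec.irregularity) + 1
            cx = rng.uniform(margin, W - margin)
            cy = rng.uniform(margin, H - margin)
            if all((cx - ox) ** 2 + (cy - oy) ** 2 > (0.8 * (margin + orad)) ** 2
                   for ox, oy, orad in centers):
                placed = True
                break
        if not placed:
            raise ValueError("overcrowded spec: could not place all nuclei")
        theta = rng.uniform(0, np.pi)
        k_lobe = rng.integers(3, 8)
        phase = rng.uniform(0, 2 * np.pi)
        dx = xs - cx
        dy = ys - cy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        rho = np.sqrt((u / r1) ** 2 + (v / r2) ** 2)
        phi = np.arctan2(v, u)
        bound = 1.0 + 0.3 * spec.irregularity * np.sin(k_lobe * phi + phase)
        mask |= rho <= bound
        centers.append((cx, cy, max(r1, r2)))
    img[mask] = spec.nucleus_mean
    if spec.noise_sd > 0:
        img += rng.normal(0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0, 255), mask


@dataclass
class SynthFeatureSpec:
    """Parameters of a backbone feature triplet.

    Defaults emulate the study's scale: 5000 images per class, 2048
    features, 64 informative columns carrying a class shift of 1.0,
    cross-backbone correlation 0.7, and noise skewness 5.5 (the regime
    of pooled ReLU features).  Tests and the acceptance script pass
    scaled-down specs explicitly.
    """

    n_per_class: int = 5000
    dim: int = 2048
    n_informative: int = 64
    class_shift: float = 1.0
    correlation: float = 0.7
    skew: float = 5.5
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.dim:
            raise ValueError("n_informative must be <= dim")
        if not 0.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must be in [0, 1]")


def _lognormal_sigma(target_skew: float) -> float:
    """Invert the lognormal skewness (w+2)sqrt(w-1), w = e^{sigma^2}."""

    def g(sig):
        w = np.exp(sig**2)
        return (w + 2) * np.sqrt(w - 1) - target_skew

    return brentq(g, 1e-3, 3.0)


def _skew_component(rng, shape, sigma):
    """Unit-variance, zero-min lognormal draw with skewness set by sigma."""
    x = rng.lognormal(mean=0.0, sigma=sigma, size=shape)
    w = np.exp(sigma**2)
    sd = np.sqrt((w - 1) * w)  # analytic lognormal sd, not the sample's
    return x / sd


def make_feature_triplet(spec: SynthFeatureSpec):
    """Draw (f50, f101, f152, labels): three correlated skewed matrices.

    Each backbone's noise is ``sqrt(rho) Z + sqrt(1 - rho) E_b`` with a
    shared component Z and independent components E_b, all lognormal
    scaled to unit variance; the component skewness is inflated so the
    *mixture* hits the spec's target.  The first ``n_informative``
    columns additionally carry ``class_shift`` on abnormal rows.  All
    entries are clipped at zero (they are non-negative by construction,
    mirroring ReLU outputs).  Labels: first block benign (0), second
    adenocarcinoma (1).
    """
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    rho = spec.correlation
    mix = rho**1.5 + (1 - rho) ** 1.5
    comp_skew = min(spec.skew / max(mix, 1e-9), 30.0)
    sigma = _lognormal_sigma(comp_skew)
    Z = _skew_component(rng, (n, spec.dim), sigma)
    labels = np.repeat([0, 1], spec.n_per_class)
    shift = np.zeros((n, spec.dim))
    shift[labels == 1, : spec.n_informative] = spec.class_shift
    mats = []
    for _ in range(3):
        E = _skew_component(rng, (n, spec.dim), sigma)
        noise = np.sqrt(rho) * Z + np.sqrt(1 - rho) * E
        mats.append(np.clip(noise + shift, 0.0, None))
    f50, f101, f152 = mats
    return f50, f101, f152, labels


def benchmark_fitness(name: str, dim: int = 5, planted=None):
    """Standard optimizer test surfaces with known optima.

    Returns a dict with ``f`` (to maximise), ``bounds``, ``optimum``
    (position, or mask for planted_subset) and ``optimum_value``.
    """
    if name == "sphere":
        return {
            "f": lambda x: -float(np.sum(np.square(x))),
            "bounds": (-5.12, 5.12),
            "optimum": np.zeros(dim),
            "optimum_value": 0.0,
        }
    if name == "rastrigin":
        def f(x):
            x = np.asarray(x, dtype=float)
            return -float(10 * x.size + np.sum(x**2 - 10 * np.cos(2 * np.pi * x)))

        return {
            "f": f,
            "bounds": (-5.12, 5.12),
            "optimum": np.zeros(dim),
            "optimum_value": 0.0,
        }
    if name == "planted_subset":
        if planted is None:
            raise ValueError("planted_subset needs a planted boolean mask")
        planted = np.asarray(planted, dtype=bool)

        def f(position):
            from .selector import position_to_mask

            keep = position_to_mask(position)
            return float(np.sum(keep & planted) / planted.sum())

        return {
            "f": f,
            "bounds": (-4.0, 4.0),
            "optimum": planted,
            "optimum_value": 1.0,
        }
    raise ValueError(f"unknown benchmark {name!r}")
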