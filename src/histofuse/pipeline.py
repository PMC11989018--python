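"""End-to-end experiment orchestration.

Binds the stages into the four experimental scenarios:

* ``none``     — descriptors computed on the raw noisy tile.
* ``seg``      — tiles are fuzzy-filtered and segmented first; descriptors
                 come from the enhanced image, the superpixel partition
                 and the nuclei ROI, which sharpens the class signal.
* ``seg_pso``  — as ``seg`` plus PSO wrapper feature selection inside the
                 training folds.
* ``seg_rdo``  — as ``seg`` plus RDO wrapper feature selection.

Because no pretrained backbone ships with the package, the three
"backbones" are jittered copies of an image-descriptor extractor padded
with uninformative skewed noise columns up to the working dimension:
RN-152-like carries the least jitter, RN-50-like the most, so fusion
weight search has a real ranking to find.  The descriptors themselves are
classic morphometrics (dark-object area fraction, object count, size
statistics, intensity moments, histogram entropy, edge density).

Everything estimated from data — standardisation, feature selection, the
classifier — is fitted on training folds only inside cross-validation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage, stats

from . import classify, evaluate, fusion, imaging, selector, slic_entropy, synthfix

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "descriptor_vector",
    "build_image_dataset",
    "extract_backbone_triplet",
    "ScenarioPipeline",
    "run_experiment",
]

SCENARIOS = ("none", "seg", "seg_pso", "seg_rdo")
# per-backbone descriptor jitter, RN-50-like noisiest
BACKBONE_JITTER = {"f152": 0.05, "f101": 0.10, "f50": 0.20}


@dataclass
class RunConfig:
    """One experiment: scenario x classifier x K values, seeded."""

    scenario: str = "seg_rdo"
    classifier: str = "knn"
    K_values: tuple[int, ...] = (5,)
    seed: int = 0
    n_per_class: int = 30
    image_size: tuple[int, int] = (64, 64)
    feature_dim: int = 24
    fusion_mode: str = "leak_free"
    weights: fusion.FusionWeights = field(default_factory=lambda: fusion.DEFAULT_WEIGHTS)
    slic_M: int = 16
    selector_budget: tuple[int, int] = (20, 10)  # population, iterations

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not set(self.K_values) <= {2, 4, 5, 8, 10}:
            raise ValueError("K values must be a subset of {2, 4, 5, 8, 10}")


def descriptor_vector(img: np.ndarray, seg: dict | None = None) -> np.ndarray:
    """Morphometric descriptors of a tile (length 10).

    Without a segmentation result the dark-object mask is a plain Otsu
    cut on the raw image; with one, the enhanced image and the superpixel
    ROI stand in, which is far less noise-sensitive.
    """
    arr = np.asarray(img, dtype=float)
    if seg is None:
        work = arr
        from skimage.filters import threshold_otsu

        dark = work < threshold_otsu(work)
    else:
        work = seg["enhanced"]
        dark = seg["roi"]
    comp, n_comp = ndimage.label(dark)
    sizes = np.bincount(comp.ravel())[1:] if n_comp else np.array([0.0])
    hist = slic_entropy.image_histogram(work)
    gy, gx = np.gradient(arr)
    from skimage.segmentation import find_boundaries

    # boundary density of the dark objects: rough nuclei have more
    # boundary per unit area than round ones
    perim = float(find_boundaries(dark.astype(int), mode="inner").sum())
    return np.array(
        [
            work.mean() / 255.0,
            work.std() / 255.0,
            float(stats.skew(work.ravel())),
            dark.mean(),  # dark-object area fraction
            float(n_comp),
            float(sizes.mean()) / dark.size,
            float(sizes.std()) / dark.size if len(sizes) > 1 else 0.0,
            selector.shannon_entropy(hist),
            float(np.hypot(gx, gy).mean()) / 255.0,
            perim / max(float(dark.sum()), 1.0),
        ]
    )


def build_image_dataset(n_per_class: int, size=(64, 64), seed: int = 0,
                        noise_sd: float = 25.0):
    """Balanced two-class tile set; returns (images, masks, labels)."""
    images, masks, labels = [], [], []
    for cls in (0, 1):
        for i in range(n_per_class):
            spec = synthfix.image_spec_for_class(
                cls, seed=seed * 100003 + cls * 1009 + i, size=size,
                noise_sd=noise_sd,
            )
            img, m = synthfix.make_image(spec)
            images.append(img)
            masks.append(m)
            labels.append(cls)
    return images, masks, np.asarray(labels)


def extract_backbone_triplet(images, use_segmentation: bool, dim: int,
                             seed: int, slic_M: int = 16):
    """Descriptor-based stand-in for the three-backbone feature stage.

    Each backbone = descriptors + backbone-specific Gaussian jitter,
    padded to ``dim`` with independent unit-variance lognormal noise
    columns (uninformative, mimicking inactive deep channels).
    """
    descs = []
    for img in images:
        if use_segmentation:
            filtered = imaging.adaptive_fuzzy_filter(img)
            seg = slic_entropy.segment(filtered, slic_entropy.SlicConfig(M=slic_M))
            descs.append(descriptor_vector(img, seg))
        else:
            descs.append(descriptor_vector(img))
    D = np.vstack(descs)
    n, base = D.shape
    if dim < base:
        raise ValueError(f"feature_dim must be >= {base}")
    scale = np.where(D.std(axis=0) > 0, D.std(axis=0), 1.0)
    out = {}
    for bi, (name, jit) in enumerate(BACKBONE_JITTER.items()):
        rng = np.random.default_rng(seed * 7919 + bi)
        mat = np.empty((n, dim))
        mat[:, :base] = D + rng.normal(0, jit, size=D.shape) * scale
        if dim > base:
            mat[:, base:] = rng.lognormal(0.0, 1.0, size=(n, dim - base))
        out[name] = mat
    return out["f50"], out["f101"], out["f152"]


class ScenarioPipeline:
    """Fold-contained model: z-scoring, optional wrapper selection, and a
    classifier, all estimated on the training fold only."""

    def __init__(self, classifier: str = "knn", selector_method: str | None = None,
                 seed: int = 0, selector_budget=(20, 10), classifier_kwargs=None):
        self.classifier_name = classifier
        self.selector_method = selector_method
        self.seed = seed
        self.selector_budget = selector_budget
        self.classifier_kwargs = classifier_kwargs or {}
        self._mu = self._sd = None
        self._mask = None
        self._clf = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self._mu = X.mean(axis=0)
        self._sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Xs = (X - self._mu) / self._sd
        if self.selector_method:
            pop, iters = self.selector_budget
            if self.selector_method == "pso":
                cfg = selector.PsoConfig(n_particles=pop, k_max=iters,
                                         r_mode="random", seed=self.seed)
            else:
                cfg = selector.RdoConfig(n_pop=pop, n_males=max(2, pop // 5),
                                         max_iter=iters, seed=self.seed)
            res = selector.select_features(Xs, y, method=self.selector_method,
                                           cfg=cfg, seed=self.seed)
            self._mask = res["mask"]
            Xs = Xs[:, self._mask]
        self._clf = classify.make_classifier(self.classifier_name, seed=self.seed,
                                             **self.classifier_kwargs)
        self._clf.fit(Xs, y)
        return self

    def predict(self, X):
        Xs = (np.asarray(X, dtype=float) - self._mu) / self._sd
        if self._mask is not None:
            Xs = Xs[:, self._mask]
        return self._clf.predict(Xs)


def run_experiment(cfg: RunConfig) -> dict:
    """Run one scenario end to end and return a results manifest.

    Generates the synthetic tiles, extracts the backbone triplet (with or
    without the segmentation stage), fuses it, cross-validates the
    fold-contained pipeline for each K, and reports per-K metric
    aggregates plus a config hash for reproducibility.
    """
    images, _, labels = build_image_dataset(
        cfg.n_per_class, size=cfg.image_size, seed=cfg.seed
    )
    use_seg = cfg.scenario != "none"
    f50, f101, f152 = extract_backbone_triplet(
        images, use_seg, cfg.feature_dim, cfg.seed, cfg.slic_M
    )
    fused = fusion.dwaff_fuse(f50, f101, f152, cfg.weights, mode="leak_free")
    sel = {"seg_pso": "pso", "seg_rdo": "rdo"}.get(cfg.scenario)
    results = {}
    for K in cfg.K_values:
        cv = evaluate.cross_validate(
            lambda: ScenarioPipeline(cfg.classifier, sel, cfg.seed,
                                     cfg.selector_budget),
            fused, labels, K=K, seed=cfg.seed,
        )
        results[K] = cv
        logger.info("scenario=%s K=%d mean accuracy %.2f%%",
                    cfg.scenario, K, cv["mean"]["accuracy"])
    cfg_dict = asdict(cfg)
    cfg_dict["weights"] = asdict(cfg.weights)
    digest = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return {
        "config": cfg_dict,
        "config_hash": digest,
        "results": {
            str(K): {"mean": cv["mean"], "sd": cv["sd"], "per_fold": cv["per_fold"]}
            for K, cv in results.items()
        },
    }
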