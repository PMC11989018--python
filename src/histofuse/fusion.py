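"""Deep-weighted averaging feature fusion (DWAFF).

Three backbone feature matrices (by convention the 2048-d global-pool
outputs of ResNet-50/101/152, but any conformable triplet works) are
combined per feature as a simplex-weighted sum, optionally divided by 3
and offset by a per-class scalar mean that widens the gap between the
benign and adenocarcinoma classes:

    fused[i, j] = (w1 f152[i,j] + w2 f101[i,j] + w3 f50[i,j]) / 3
                  + mean_class(j)          (faithful mode)

    fused[i, j] =  w1 f152[i,j] + w2 f101[i,j] + w3 f50[i,j]
                                            (leak-free mode)

The class-mean offset requires labels, so faithful mode is only valid when
the offsets were estimated on training data; leak-free mode is a plain
convex combination usable at inference.  Weights are found by grid search
on the simplex, scoring each candidate by mean K-fold accuracy of a
KNN(k=5) reference classifier; the study's operating point is
(w1, w2, w3) = (0.45, 0.35, 0.20) for RN-152/101/50.

No backbone is implemented here: ``extract_features`` adapts any
user-supplied callable that maps one image to a fixed-length vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "FusionWeights",
    "ClassMeans",
    "DEFAULT_WEIGHTS",
    "extract_features",
    "class_mean_offsets",
    "dwaff_fuse",
    "search_fusion_weights",
    "feature_statistics",
]


@dataclass(frozen=True)
class FusionWeights:
    """Simplex weights (w1 -> RN-152, w2 -> RN-101, w3 -> RN-50)."""

    w1: float
    w2: float
    w3: float

    def __post_init__(self):
        for w in (self.w1, self.w2, self.w3):
            if not 0.0 <= w <= 1.0:
                raise ValueError("weights must lie in [0, 1]")
        if abs(self.w1 + self.w2 + self.w3 - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


DEFAULT_WEIGHTS = FusionWeights(0.45, 0.35, 0.20)


@dataclass(frozen=True)
class ClassMeans:
    """Scalar grand-mean offsets for the two classes (0=normal, 1=abnormal)."""

    mean_normal: float
    mean_abnormal: float


def _as_matrix(f) -> np.ndarray:
    arr = np.asarray(f, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"feature matrix must be 2-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature matrix contains non-finite values")
    return arr


def _conformable(f50, f101, f152):
    a, b, c = _as_matrix(f50), _as_matrix(f101), _as_matrix(f152)
    if not (a.shape == b.shape == c.shape):
        raise ValueError(
            f"backbone matrices must agree in shape: {a.shape}, {b.shape}, {c.shape}"
        )
    return a, b, c


def extract_features(images, extractor) -> np.ndarray:
    """Adapter: run ``extractor`` (image -> 1-D vector) over a list of images.

    Output row order follows input order; the vector length must be
    consistent across images or a contract-violation error is raised.
    """
    rows = []
    d = None
    for i, img in enumerate(images):
        v = np.asarray(extractor(img), dtype=float).ravel()
        if d is None:
            d = v.size
        elif v.size != d:
            raise ValueError(
                f"extractor contract violation: image {i} gave length "
                f"{v.size}, expected {d}"
            )
        rows.append(v)
    return np.vstack(rows)


def class_mean_offsets(f50, f101, f152, labels) -> ClassMeans:
    """Per-class scalar offsets: backbone-averaged grand means.

    For each class, the grand mean of all feature entries of that class's
    rows is taken in each backbone, and the three scalars are averaged.
    """
    a, b, c = _conformable(f50, f101, f152)
    y = np.asarray(labels).astype(int)
    if y.shape[0] != a.shape[0]:
        raise ValueError("label count must equal row count")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    means = []
    for cls in (0, 1):
        sel = y == cls
        means.append(float(np.mean([a[sel].mean(), b[sel].mean(), c[sel].mean()])))
    return ClassMeans(mean_normal=means[0], mean_abnormal=means[1])


def dwaff_fuse(
    f50,
    f101,
    f152,
    weights: FusionWeights = DEFAULT_WEIGHTS,
    labels=None,
    means: ClassMeans | None = None,
    mode: str = "leak_free",
    divide_by_three: bool = True,
) -> np.ndarray:
    """Fuse three backbone matrices into one.

    ``faithful`` mode applies the /3 divisor (configurable) and adds the
    class-mean offset of each row's label — it needs ``labels`` and
    ``means`` and is only leakage-safe when the means come from training
    folds.  ``leak_free`` mode is the plain weighted sum (no /3, no
    offset) and needs neither.
    """
    a, b, c = _conformable(f50, f101, f152)
    w = weights
    fused = w.w1 * c + w.w2 * b + w.w3 * a
    if mode == "leak_free":
        return fused
    if mode != "faithful":
        raise ValueError(f"unknown mode {mode!r}")
    if labels is None or means is None:
        raise ValueError("faithful mode requires labels and class means")
    if divide_by_three:
        fused = fused / 3.0
    y = np.asarray(labels).astype(int)
    offs = np.where(y == 0, means.mean_normal, means.mean_abnormal)
    return fused + offs[:, None]


def _simplex_grid(step: float):
    """All (w1, w2, w3) with wi >= 0 summing to 1 on a step grid."""
    n = int(round(1.0 / step))
    pts = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            k = n - i - j
            pts.append((i / n, j / n, k / n))
    return pts


def _knn_cv_accuracy(X, y, K, seed) -> float:
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        clf = KNeighborsClassifier(n_neighbors=min(5, len(tr)))
        clf.fit(X[tr], y[tr])
        accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def search_fusion_weights(
    f50,
    f101,
    f152,
    labels,
    K_values=(5,),
    grid_step: float = 0.05,
    seed: int = 0,
):
    """Grid search over simplex weights by reference-classifier CV accuracy.

    Every (w1, w2, w3) on the ``grid_step`` simplex grid is scored by the
    mean K-fold accuracy of KNN(k=5) on the leak-free fused features,
    averaged over ``K_values``.  Ties break to larger w1, then larger w2
    (the RN-152-first backbone ranking).  Returns (best FusionWeights,
    score table as a list of dicts).
    """
    if grid_step not in (0.05, 0.1):
        raise ValueError("grid_step must be 0.05 or 0.1")
    if not set(K_values) <= {2, 4, 5, 8, 10}:
        raise ValueError("K_values must be a subset of {2, 4, 5, 8, 10}")
    a, b, c = _conformable(f50, f101, f152)
    y = np.asarray(labels).astype(int)
    grid = _simplex_grid(grid_step)
    if not grid:
        raise ValueError("empty weight grid")
    table = []
    best = None
    for (w1, w2, w3) in grid:
        fused = w1 * c + w2 * b + w3 * a
        score = float(
            np.mean([_knn_cv_accuracy(fused, y, K, seed) for K in K_values])
        )
        table.append({"w1": w1, "w2": w2, "w3": w3, "score": score})
        key = (score, w1, w2)
        if best is None or key > best[0]:
            best = (key, FusionWeights(w1, w2, w3))
    return best[1], table


def feature_statistics(f, labels) -> dict:
    """Descriptive statistics of a feature matrix, per class.

    Per class: grand mean, sample variance, moment skewness and (raw)
    kurtosis of all entries pooled.  Across classes: Pearson correlation
    between the per-image feature-mean vectors of the two classes
    (truncated to equal length) and the Dice coefficient of the
    above-grand-mean binarised per-feature mean profiles.
    """
    X = _as_matrix(f)
    y = np.asarray(labels).astype(int)
    out: dict = {}
    profiles = {}
    img_means = {}
    for cls in (0, 1):
        sel = y == cls
        if sel.sum() < 2:
            raise ValueError("need >= 2 rows per class")
        vals = X[sel].ravel()
        rec = {
            "mean": float(vals.mean()),
            "variance": float(vals.var(ddof=1)),
        }
        if np.allclose(vals, vals[0]):
            rec.update(skewness=0.0, kurtosis=0.0, degenerate=True)
        else:
            rec.update(
                skewness=float(stats.skew(vals)),
                kurtosis=float(stats.kurtosis(vals, fisher=False)),
                degenerate=False,
            )
        out["normal" if cls == 0 else "abnormal"] = rec
        profiles[cls] = X[sel].mean(axis=0)
        img_means[cls] = X[sel].mean(axis=1)
    n = min(len(img_means[0]), len(img_means[1]))
    v0, v1 = img_means[0][:n], img_means[1][:n]
    if np.std(v0) == 0 or np.std(v1) == 0:
        out["pcc"] = 1.0 if np.allclose(v0, v1) else 0.0
    else:
        out["pcc"] = float(np.corrcoef(v0, v1)[0, 1])
    grand = X.mean()
    m0 = profiles[0] > grand
    m1 = profiles[1] > grand
    denom = m0.sum() + m1.sum()
    out["dice"] = float(2.0 * np.sum(m0 & m1) / denom) if denom else 1.0
    return out
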