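"""K-fold cross-validation and confusion-matrix metrics.

The clinical convention here makes *benign* (label 0) the positive class:
TP counts benign tumours correctly called benign, TN counts
adenocarcinomas correctly called adenocarcinoma, FP is an adenocarcinoma
called benign, FN a benign tumour called adenocarcinoma.

Seven metrics are reported per confusion matrix: accuracy, error rate,
F1, MCC, Jaccard index, G-mean (sqrt of sensitivity x specificity) and
Cohen's kappa.  Percent-scale metrics are on [0, 100]; MCC and kappa on
[-1, 1].  A metric whose denominator vanishes is reported as 0 together
with an ``undefined`` flag listing the affected names.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionMatrix",
    "kfold_plan",
    "confusion",
    "metrics",
    "cross_validate",
    "boundary_recall",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def kfold_plan(n: int, labels, K: int, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment: per-sample fold index in 0..K-1.

    Folds partition the samples, sizes differ by at most one, and each
    fold mirrors the class balance.  Reproducible by seed.
    """
    y = np.asarray(labels).astype(int)
    if y.shape[0] != n:
        raise ValueError("labels length must equal n")
    counts = np.bincount(y)
    if K > counts[counts > 0].min():
        raise ValueError("K exceeds the smallest class count")
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    folds = np.empty(n, dtype=int)
    for k, (_, te) in enumerate(skf.split(np.zeros((n, 1)), y)):
        folds[te] = k
    return folds


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Tally the confusion matrix with benign (0) as the positive class."""
    t = np.asarray(y_true).astype(int)
    p = np.asarray(y_pred).astype(int)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    for v in np.concatenate([t, p]):
        if v not in (0, 1):
            raise ValueError("labels must be 0 (benign) or 1 (ACA)")
    return ConfusionMatrix(
        TP=int(np.sum((t == 0) & (p == 0))),
        TN=int(np.sum((t == 1) & (p == 1))),
        FP=int(np.sum((t == 1) & (p == 0))),
        FN=int(np.sum((t == 0) & (p == 1))),
    )


def _safe_div(num, den):
    return (num / den, False) if den != 0 else (0.0, True)


def metrics(cm: ConfusionMatrix) -> dict:
    """The seven-metric suite of a binary confusion matrix.

    Percent metrics (accuracy, error_rate, f1, jaccard, g_mean) are on
    the 0-100 scale; mcc and kappa on [-1, 1].  Undefined ratios are
    reported as 0 and named in the ``undefined`` list.
    """
    TP, TN, FP, FN = cm.TP, cm.TN, cm.FP, cm.FN
    total = cm.total
    if total <= 0:
        raise ValueError("empty confusion matrix")
    undefined = []

    acc = (TP + TN) / total * 100.0
    err = (FP + FN) / total * 100.0
    f1, bad = _safe_div(2 * TP, 2 * TP + FP + FN)
    if bad:
        undefined.append("f1")
    jac, bad = _safe_div(TP, TP + FP + FN)
    if bad:
        undefined.append("jaccard")
    sens, bad_s = _safe_div(TP, TP + FN)
    spec, bad_p = _safe_div(TN, TN + FP)
    if bad_s or bad_p:
        undefined.append("g_mean")
    gmean = np.sqrt(sens * spec)
    mcc_den = np.sqrt(
        float(TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    )
    if mcc_den == 0:
        mcc = 0.0
        undefined.append("mcc")
    else:
        mcc = (TN * TP - FN * FP) / mcc_den
    pr_a = (TP + TN) / total
    pr_e = ((TP + FP) * (TP + FN) + (TN + FN) * (TN + FP)) / total**2
    if pr_e == 1.0:
        kappa = 0.0
        undefined.append("kappa")
    else:
        kappa = (pr_a - pr_e) / (1.0 - pr_e)
    return {
        "accuracy": acc,
        "error_rate": err,
        "f1": f1 * 100.0,
        "jaccard": jac * 100.0,
        "g_mean": gmean * 100.0,
        "mcc": float(mcc),
        "kappa": float(kappa),
        "undefined": undefined,
    }


def boundary_recall(gt_mask, labels, tol: int = 2) -> float:
    """Fraction of ground-truth boundary pixels within ``tol`` pixels of a
    predicted segment boundary — the standard superpixel boundary-recall
    score against a binary ground-truth mask."""
    from scipy.ndimage import binary_dilation
    from skimage.segmentation import find_boundaries

    gt_b = find_boundaries(np.asarray(gt_mask).astype(int), mode="inner")
    if not gt_b.any():
        return 1.0
    pred_b = find_boundaries(np.asarray(labels).astype(int), mode="thick")
    near = binary_dilation(pred_b, iterations=tol) if tol > 0 else pred_b
    return float(np.sum(gt_b & near) / gt_b.sum())


def cross_validate(pipeline_factory, X, y, K: int = 5, seed: int = 0):
    """Stratified K-fold evaluation of a fold-contained pipeline.

    ``pipeline_factory()`` must return a fresh object exposing
    ``fit(X, y)`` and ``predict(X)``; anything estimated inside the
    pipeline (class-mean offsets, weight search, feature selection) sees
    training folds only, so no test-fold information leaks into the fit.

    Returns a dict with ``per_fold`` metric dicts and ``mean``/``sd``
    aggregates over the numeric metrics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    folds = kfold_plan(len(y), y, K, seed)
    per_fold = []
    for k in range(K):
        te = folds == k
        tr = ~te
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {k}: training data has a single class")
        model = pipeline_factory()
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        per_fold.append(metrics(confusion(y[te], pred)))
    keys = ["accuracy", "error_rate", "f1", "jaccard", "g_mean", "mcc", "kappa"]
    agg = {
        "mean": {k: float(np.mean([m[k] for m in per_fold])) for k in keys},
        "sd": {k: float(np.std([m[k] for m in per_fold], ddof=1)) if K > 1 else 0.0
               for k in keys},
    }
    return {"per_fold": per_fold, **agg}
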