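"""Entropy-guided SLIC superpixel segmentation on grayscale tiles.

The segmenter runs in six stages:

1. Kapur maximum-entropy multilevel thresholding of the intensity
   histogram (``image_histogram`` -> ``max_entropy_thresholds``).  The k
   thresholds that maximise the summed Shannon entropies of the k+1
   histogram segments mark the intensity strata of the tissue.
2. Piecewise power-law contrast enhancement (``contrast_enhance``): each
   intensity interval between thresholds is stretched onto an equal share
   of [1, 255] through a curve ``f(x) = a x^r + b`` fitted to the interval
   endpoints, split at the probability-weighted interval centroid so the
   curve has its turning point at the interval's mass centre.
3. Grid seeding with spacing ``S = sqrt(N / M)`` and relocation of each
   seed to the minimum-gradient position in its 3x3 neighbourhood.
4. Localised k-means in (x, y, gs) space: pixels inside a *circular*
   window of radius S around each centre (cells are round, so a round
   search window fits them) are assigned to the centre minimising
   ``d' = sqrt(d_spatial^2 + alpha * d_gray^2)``, and centres are updated
   to their cluster means until displacement stalls.
5. Small-superpixel merging: connected fragments below a minimum size are
   absorbed into the adjacent segment sharing the longest boundary.
6. Optional ROI extraction: superpixels whose mean enhanced intensity is
   below the global Otsu threshold are flagged as nuclei-dense regions.

``alpha`` follows the grayscale-weighted distance with default
``alpha = (S / m)^2`` for compactness ``m`` in [1, 40]; the conventional
SLIC normalisation ``sqrt(d_g^2 + (d_s / S)^2 m^2)`` is available via
``distance_mode="standard"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import find_boundaries

logger = logging.getLogger(__name__)

__all__ = [
    "SlicConfig",
    "image_histogram",
    "segmented_entropy",
    "max_entropy_thresholds",
    "interval_turning_point",
    "enhancement_curve",
    "contrast_enhance",
    "grid_init_centers",
    "pixel_distance",
    "slic_iterate",
    "merge_small_superpixels",
    "segment",
    "roi_mask",
    "boundary_overlay",
]


@dataclass
class SlicConfig:
    """Parameters of the segmenter.

    M : target superpixel count (the realised grid count may differ).
    compactness : m in [1, 40]; trades spatial regularity against
        intensity adherence.  Default 20 (mid-range).
    k_thresholds : number of entropy thresholds (1..4).
    r_power : exponent of the enhancement curves (>= 1).
    alpha_override : use this alpha in the distance instead of (S/m)^2.
    distance_mode : "grayscale_scaled" (d' = sqrt(ds^2 + alpha dg^2),
        default) or "standard" (classic SLIC normalisation).
    min_size_frac : minimum segment size as a fraction of S^2
        (default 0.25, i.e. floor(S^2/4) pixels).
    """

    M: int = 64
    compactness: float = 20.0
    k_thresholds: int = 2
    r_power: float = 2.0
    max_iter: int = 10
    conv_tol: float = 0.5
    min_size_frac: float = 0.25
    alpha_override: float | None = None
    distance_mode: str = "grayscale_scaled"
    enhance: bool = True

    def __post_init__(self):
        if self.M < 4:
            raise ValueError("M must be >= 4")
        if not 1.0 <= self.compactness <= 40.0:
            raise ValueError("compactness must be in [1, 40]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


# ---------------------------------------------------------------------------
# Stage 1: histogram and Kapur entropy thresholding
# ---------------------------------------------------------------------------

def image_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin intensity probability distribution of a grayscale image."""
    arr = np.asarray(img)
    if arr.size == 0:
        raise ValueError("empty image")
    idx = np.clip(np.round(arr).astype(int), 0, 255)
    counts = np.bincount(idx.ravel(), minlength=256).astype(float)
    return counts / counts.sum()


def _segment_slices(thresholds) -> list[tuple[int, int]]:
    """Inclusive bin ranges [lo, hi] of the k+1 segments cut at thresholds.

    Threshold t puts bins 0..t in the left segment and t+1.. in the right.
    """
    th = list(thresholds)
    bounds = [0] + [t + 1 for t in th] + [256]
    return [(bounds[i], bounds[i + 1] - 1) for i in range(len(bounds) - 1)]


def segmented_entropy(hist: np.ndarray, thresholds) -> float:
    """Kapur objective: summed Shannon entropies of histogram segments.

    phi = sum over segments of [log P_seg - (sum p log p) / P_seg] with
    P_seg the segment's total mass and 0·log 0 := 0.  Raises if any segment
    carries zero mass (the threshold tuple is infeasible).
    """
    p = np.asarray(hist, dtype=float)
    phi = 0.0
    for lo, hi in _segment_slices(thresholds):
        seg = p[lo : hi + 1]
        P = seg.sum()
        if P <= 0.0:
            raise ValueError(f"empty histogram segment [{lo}, {hi}]")
        nz = seg[seg > 0]
        phi += np.log(P) - float(np.sum(nz * np.log(nz))) / P
    return float(phi)


def _kapur_terms(hist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative mass and cumulative p·log p for fast segment entropies."""
    p = np.asarray(hist, dtype=float)
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return np.concatenate([[0.0], np.cumsum(p)]), np.concatenate(
        [[0.0], np.cumsum(plogp)]
    )


def _phi_from_cum(cumP, cumL, thresholds) -> float:
    phi = 0.0
    bounds = [0] + [t + 1 for t in thresholds] + [256]
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        P = cumP[hi] - cumP[lo]
        if P <= 0.0:
            return -np.inf
        phi += np.log(P) - (cumL[hi] - cumL[lo]) / P
    return phi


def max_entropy_thresholds(hist: np.ndarray, k: int) -> list[int]:
    """Thresholds maximising the Kapur segmented entropy.

    Exhaustive search for k <= 2 (exact); coordinate ascent from quantile
    initialisation for k >= 3, with phi non-decreasing each sweep.  Ties
    break to the lexicographically smallest tuple.
    """
    if not 1 <= k <= 4:
        raise ValueError("k must be in 1..4")
    p = np.asarray(hist, dtype=float)
    if int(np.count_nonzero(p)) < k + 1:
        raise ValueError("histogram has fewer non-empty bins than segments")
    cumP, cumL = _kapur_terms(p)

    # vectorised per-segment term phi(lo, hi] = log P - (cum p log p)/P
    def seg_term(lo, hi):
        P = cumP[hi] - cumP[lo]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(P > 0, np.log(np.where(P > 0, P, 1.0))
                           - (cumL[hi] - cumL[lo]) / np.where(P > 0, P, 1.0),
                           -np.inf)
        return out

    t = np.arange(1, 255)  # thresholds strictly inside (0, 255)
    if k == 1:
        phi = seg_term(np.zeros_like(t), t + 1) + seg_term(t + 1, np.full_like(t, 256))
        if not np.any(np.isfinite(phi)):
            raise ValueError("no feasible threshold")
        return [int(t[np.argmax(phi)])]
    if k == 2:
        t1 = t[:, None]
        t2 = t[None, :]
        phi = (
            seg_term(np.zeros_like(t1), t1 + 1)
            + seg_term(t1 + 1, t2 + 1)
            + seg_term(t2 + 1, np.full_like(t2, 256))
        )
        phi = np.where(t2 > t1, phi, -np.inf)
        if not np.any(np.isfinite(phi)):
            raise ValueError("no feasible threshold pair")
        i, j = np.unravel_index(np.argmax(phi), phi.shape)
        return [int(t[i]), int(t[j])]

    # k >= 3: quantile init, then coordinate ascent.
    cdf = np.cumsum(p)
    th = []
    for i in range(1, k + 1):
        q = i / (k + 1)
        t = int(np.searchsorted(cdf, q))
        th.append(min(max(t, 1), 254))
    th = sorted(set(th))
    while len(th) < k:  # collapse-proof the init
        for t in range(1, 255):
            if t not in th:
                th.append(t)
                break
        th.sort()
    best_phi = _phi_from_cum(cumP, cumL, th)
    improved = True
    while improved:
        improved = False
        for i in range(k):
            lo = th[i - 1] + 1 if i > 0 else 1
            hi = th[i + 1] - 1 if i < k - 1 else 254
            for t in range(lo, hi + 1):
                trial = th[:i] + [t] + th[i + 1 :]
                phi = _phi_from_cum(cumP, cumL, trial)
                if phi > best_phi + 1e-12:
                    th, best_phi = trial, phi
                    improved = True
    if not np.isfinite(best_phi):
        raise ValueError("no feasible threshold tuple found")
    return th


# ---------------------------------------------------------------------------
# Stage 2: interval contrast enhancement
# ---------------------------------------------------------------------------

def interval_turning_point(hist: np.ndarray, x_lo: int, x_hi: int) -> float:
    """Probability-weighted centroid of the histogram over [x_lo, x_hi]."""
    p = np.asarray(hist, dtype=float)[x_lo : x_hi + 1]
    mass = p.sum()
    if mass <= 0:
        raise ValueError(f"interval [{x_lo}, {x_hi}] carries no mass")
    x = np.arange(x_lo, x_hi + 1, dtype=float)
    return float(np.sum(x * p) / mass)


def enhancement_curve(
    x_lo: float, x_hi: float, y_lo: float, y_hi: float, r: float
) -> tuple[float, float]:
    """Coefficients (a, b) of f(x) = a x^r + b through both endpoints."""
    if x_hi <= x_lo or x_lo < 1:
        raise ValueError("need x_hi > x_lo >= 1")
    if y_hi <= y_lo:
        raise ValueError("need y_hi > y_lo")
    if r < 1:
        raise ValueError("r must be >= 1")
    denom = x_hi**r - x_lo**r
    if denom == 0:
        raise ValueError("degenerate interval: x_hi^r == x_lo^r")
    a = (y_hi - y_lo) / denom
    b = y_lo - a * x_lo**r
    return a, b


def _enhancement_pieces(hist, thresholds, r):
    """Per-interval two-piece power curves.

    Interval bounds X = [1, t1, ..., tk, 255]; target bounds Y partition
    [1, 255] equally.  Each interval splits at its mass centroid X_m, which
    maps to the target midpoint Y_m, giving the S-shaped (convex then
    concave w.r.t. the mass centre) transfer the enhancement calls for.
    Returns a list of (x_lo, x_hi, a, b, r) pieces ordered by x.
    """
    th = list(thresholds)
    xb = [1.0] + [float(t) for t in th] + [255.0]
    yb = list(np.linspace(1.0, 255.0, len(xb)))
    pieces = []
    for i in range(len(xb) - 1):
        x_lo, x_hi = xb[i], xb[i + 1]
        y_lo, y_hi = yb[i], yb[i + 1]
        if x_hi <= x_lo:
            continue
        try:
            x_m = interval_turning_point(hist, int(np.ceil(x_lo)), int(x_hi))
        except ValueError:
            x_m = 0.5 * (x_lo + x_hi)
        y_m = 0.5 * (y_lo + y_hi)
        if x_lo + 0.5 < x_m < x_hi - 0.5:
            a1, b1 = enhancement_curve(x_lo, x_m, y_lo, y_m, r)
            a2, b2 = enhancement_curve(x_m, x_hi, y_m, y_hi, r)
            pieces.append((x_lo, x_m, a1, b1, r))
            pieces.append((x_m, x_hi, a2, b2, r))
        else:  # centroid at an endpoint: single curve over the interval
            a, b = enhancement_curve(x_lo, x_hi, y_lo, y_hi, r)
            pieces.append((x_lo, x_hi, a, b, r))
    return pieces


def contrast_enhance(img: np.ndarray, thresholds, r: float = 2.0) -> np.ndarray:
    """Piecewise power-law contrast enhancement between entropy thresholds.

    Monotone non-decreasing in the input intensity; endpoints of each
    interval map onto the equal-width target intervals spanning [1, 255].
    Intensities are first shifted into the curve domain x >= 1.
    """
    arr = np.asarray(img, dtype=float)
    hist = image_histogram(arr)
    pieces = _enhancement_pieces(hist, thresholds, r)
    x = np.clip(arr, 1.0, 255.0)
    out = np.empty_like(x)
    for j, (x_lo, x_hi, a, b, rr) in enumerate(pieces):
        if j == 0:
            mask = (x >= x_lo) & (x <= x_hi)
        else:
            mask = (x > x_lo) & (x <= x_hi)
        out[mask] = a * x[mask] ** rr + b
    return np.clip(out, 0.0, 255.0)


# ---------------------------------------------------------------------------
# Stage 3: seeding
# ---------------------------------------------------------------------------

def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(np.asarray(img, dtype=float))
    return np.hypot(gx, gy)


def grid_init_centers(img: np.ndarray, M: int):
    """Seed cluster centres on a regular grid, nudged off gradients.

    Spacing S = sqrt(N/M); each centre then moves to the position of
    minimum gradient magnitude in its 3x3 neighbourhood (ties keep the
    original position).  Returns an (M', 3) float array of rows
    (x, y, gs) — M' is the realised grid count.
    """
    arr = np.asarray(img, dtype=float)
    H, W = arr.shape
    N = H * W
    if M > N // 4:
        raise ValueError("M too large for image size")
    S = np.sqrt(N / M)
    nx = max(1, int(round(W / S)))
    ny = max(1, int(round(H / S)))
    grad = _gradient_magnitude(arr)
    centers = []
    for iy in range(ny):
        for ix in range(nx):
            cx = int((ix + 0.5) * W / nx)
            cy = int((iy + 0.5) * H / ny)
            cx = min(cx, W - 1)
            cy = min(cy, H - 1)
            best = (cy, cx)
            best_g = grad[cy, cx]
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    y, x = cy + dy, cx + dx
                    if 0 <= y < H and 0 <= x < W and grad[y, x] < best_g - 1e-12:
                        best, best_g = (y, x), grad[y, x]
            centers.append((float(best[1]), float(best[0]), arr[best]))
    return np.asarray(centers, dtype=float)


# ---------------------------------------------------------------------------
# Stage 4: clustering
# ---------------------------------------------------------------------------

def pixel_distance(
    cx: float, cy: float, cg: float, px: float, py: float, pg: float, alpha: float
) -> float:
    """Joint spatial-grayscale distance d' = sqrt(ds^2 + alpha * dg^2)."""
    ds2 = (cx - px) ** 2 + (cy - py) ** 2
    dg2 = (cg - pg) ** 2
    return float(np.sqrt(ds2 + alpha * dg2))


def _resolve_alpha(cfg: SlicConfig, S: float) -> float:
    if cfg.alpha_override is not None:
        return float(cfg.alpha_override)
    return (S / cfg.compactness) ** 2


def slic_iterate(img: np.ndarray, centers: np.ndarray, cfg: SlicConfig):
    """Localised k-means over circular windows of radius S.

    Assignment pass: for each centre (in label order; lower label wins
    ties), pixels within Euclidean spatial distance S get the centre's
    label if its d' beats the best seen.  Pixels outside every window are
    assigned to the globally nearest centre by d'.  Update pass: each
    centre moves to the mean (x, y, gs) of its pixels.  Stops when the
    mean centre displacement drops below ``conv_tol`` or after
    ``max_iter`` rounds.

    Returns (labels, centers, converged).
    """
    arr = np.asarray(img, dtype=float)
    H, W = arr.shape
    N = H * W
    S = np.sqrt(N / cfg.M)
    alpha = _resolve_alpha(cfg, S)
    standard = cfg.distance_mode == "standard"
    m = cfg.compactness
    C = np.array(centers, dtype=float, copy=True)
    n_c = len(C)
    ys, xs = np.mgrid[0:H, 0:W]
    labels = np.full((H, W), -1, dtype=int)
    best = np.full((H, W), np.inf)
    converged = False

    for it in range(cfg.max_iter):
        labels.fill(-1)
        best.fill(np.inf)
        for i in range(n_c):
            cx, cy, cg = C[i]
            x0, x1 = max(0, int(cx - S)), min(W, int(np.ceil(cx + S)) + 1)
            y0, y1 = max(0, int(cy - S)), min(H, int(np.ceil(cy + S)) + 1)
            sub_y, sub_x = np.mgrid[y0:y1, x0:x1]
            ds2 = (sub_x - cx) ** 2 + (sub_y - cy) ** 2
            circ = ds2 <= S * S
            if not circ.any():
                continue
            dg2 = (arr[y0:y1, x0:x1] - cg) ** 2
            if standard:
                d = np.sqrt(dg2 + ds2 / (S * S) * (m * m))
            else:
                d = np.sqrt(ds2 + alpha * dg2)
            win_best = best[y0:y1, x0:x1]
            upd = circ & (d < win_best - 1e-12)
            win_best[upd] = d[upd]
            lbl = labels[y0:y1, x0:x1]
            lbl[upd] = i
        # corners may fall outside every circular window
        un = labels < 0
        if un.any():
            uy, ux = np.nonzero(un)
            for y, x in zip(uy, ux):
                ds2 = (C[:, 0] - x) ** 2 + (C[:, 1] - y) ** 2
                dg2 = (C[:, 2] - arr[y, x]) ** 2
                if standard:
                    d = np.sqrt(dg2 + ds2 / (S * S) * (m * m))
                else:
                    d = np.sqrt(ds2 + alpha * dg2)
                labels[y, x] = int(np.argmin(d))
                best[y, x] = float(d.min())
        newC = C.copy()
        for i in range(n_c):
            mask = labels == i
            if mask.any():
                newC[i, 0] = xs[mask].mean()
                newC[i, 1] = ys[mask].mean()
                newC[i, 2] = arr[mask].mean()
        disp = np.sqrt(((newC[:, :2] - C[:, :2]) ** 2).sum(axis=1)).mean()
        C = newC
        if disp < cfg.conv_tol:
            converged = True
            break
    if not converged:
        logger.info("slic_iterate hit max_iter=%d without convergence", cfg.max_iter)
    return labels, C, converged


# ---------------------------------------------------------------------------
# Stage 5: merging
# ---------------------------------------------------------------------------

def _compact_labels(labels: np.ndarray) -> np.ndarray:
    uniq, inv = np.unique(labels, return_inverse=True)
    return inv.reshape(labels.shape)


def merge_small_superpixels(labels: np.ndarray, min_size: int) -> np.ndarray:
    """Absorb connected fragments below ``min_size`` into their neighbours.

    Each undersized connected component is relabeled to the adjacent
    segment sharing the longest boundary (4-connectivity); ties go to the
    smaller label.  Repeats until no undersized fragment remains (unless
    the whole image is a single segment), then compacts labels to 0..n-1.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    lab = np.array(labels, dtype=int, copy=True)
    H, W = lab.shape
    while True:
        # split every label into its connected components
        comp = np.full_like(lab, -1)
        n_comp = 0
        for val in np.unique(lab):
            cc, n = ndimage.label(lab == val)
            comp[cc > 0] = cc[cc > 0] + n_comp - 1
            n_comp += n
        sizes = np.bincount(comp.ravel(), minlength=n_comp)
        small = [c for c in range(n_comp) if sizes[c] < min_size]
        if not small or n_comp == 1:
            break
        small_set = sorted(small, key=lambda c: sizes[c])
        merged_any = False
        for c in small_set:
            mask = comp == c
            if not mask.any():
                continue
            # boundary contact counts with each neighbouring label
            contact: dict[int, int] = {}
            yy, xx = np.nonzero(mask)
            for y, x in zip(yy, xx):
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ny, nx_ = y + dy, x + dx
                    if 0 <= ny < H and 0 <= nx_ < W and not mask[ny, nx_]:
                        nl = lab[ny, nx_]
                        contact[nl] = contact.get(nl, 0) + 1
            if not contact:
                continue
            best_len = max(contact.values())
            target = min(l for l, n in contact.items() if n == best_len)
            lab[mask] = target
            merged_any = True
        if not merged_any:
            break
    return _compact_labels(lab)


# ---------------------------------------------------------------------------
# Stage 6: orchestration, ROI, overlay
# ---------------------------------------------------------------------------

def roi_mask(enhanced: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Nuclei-dense region mask: superpixels darker than the Otsu cut.

    Superpixels whose mean enhanced intensity falls below the global Otsu
    threshold are kept (nuclei stain dark).  Heuristic region-of-interest
    extraction on top of the superpixel partition.
    """
    arr = np.asarray(enhanced, dtype=float)
    n = int(labels.max()) + 1
    means = ndimage.mean(arr, labels=labels, index=np.arange(n))
    if np.allclose(means, means[0]):
        return np.ones_like(labels, dtype=bool)
    cut = threshold_otsu(arr)
    keep = means < cut
    return keep[labels]


def boundary_overlay(img: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Grayscale image with superpixel boundaries burned in at 255."""
    out = np.asarray(img, dtype=float).copy()
    out[find_boundaries(labels, mode="thick")] = 255.0
    return out


def segment(img: np.ndarray, cfg: SlicConfig | None = None):
    """Full entropy-guided SLIC pipeline on a grayscale image.

    Returns a dict with keys ``labels`` (H×W int), ``centers``,
    ``thresholds``, ``enhanced``, ``roi`` (bool mask), ``overlay`` and
    ``converged``.  Deterministic given image and config.
    """
    cfg = cfg or SlicConfig()
    arr = np.asarray(img, dtype=float)
    hist = image_histogram(arr)
    try:
        th = max_entropy_thresholds(hist, cfg.k_thresholds)
    except ValueError:
        th = []  # near-constant image: nothing to threshold
    enhanced = contrast_enhance(arr, th, cfg.r_power) if (cfg.enhance and th) else arr
    centers = grid_init_centers(enhanced, cfg.M)
    labels, centers, converged = slic_iterate(enhanced, centers, cfg)
    S = np.sqrt(arr.size / cfg.M)
    min_size = max(1, int(cfg.min_size_frac * S * S))
    labels = merge_small_superpixels(labels, min_size)
    return {
        "labels": labels,
        "centers": centers,
        "thresholds": th,
        "enhanced": enhanced,
        "roi": roi_mask(enhanced, labels),
        "overlay": boundary_overlay(arr, labels),
        "converged": converged,
    }
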