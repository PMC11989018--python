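"""Selective feature pooling: PSO/RDO wrapper selection and entropy measures.

Two population metaheuristics search a continuous box for the position
maximising a fitness function.  For feature selection the position has one
coordinate per feature, decoded to a keep/drop mask by a sigmoid threshold
at zero, and the fitness is the cross-validated accuracy of a cheap
reference classifier on the masked features minus a sparsity penalty —
the classic wrapper formulation.

PSO (particle swarm) uses the velocity rule
``q <- w q + c1 r1 (pbest - p) + c2 r2 (gbest - p)`` with the inertia
weight decaying linearly from w_max to w_min.  The r factors are fixed at
0.85 by default (``r_mode="fixed"``, the configuration the study states);
``r_mode="random"`` restores the conventional per-step uniform draws.

RDO (red deer) ranks the population into males and hinds; the top
``gamma`` share of males are commanders, the rest stags.  Males roar
(random local moves, accepted greedily), commanders fight stags (best of
the pair and two blend points wins), harems of hinds are allotted to
commanders proportionally to fitness, and offspring are midpoint blends
with uniform noise.  Elitist survivor selection keeps the population size
fixed, so the best score never decreases.

Approximate, Shannon and fuzzy entropy summarise the regularity of a
selected feature set (flattened row-major into a series).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "PsoConfig",
    "RdoConfig",
    "inertia_weight",
    "pso_optimize",
    "position_to_mask",
    "roaring_update",
    "fight_update",
    "harem_allocation",
    "offspring_update",
    "rdo_optimize",
    "select_features",
    "approximate_entropy",
    "shannon_entropy",
    "fuzzy_entropy",
]


@dataclass
class PsoConfig:
    """Particle-swarm parameters (defaults follow the stated ranges:
    inertia 0.45..0.9, c1=c2 in [1, 2], r1=r2 fixed at 0.85)."""

    n_particles: int = 30
    k_max: int = 100
    w_min: float = 0.45
    w_max: float = 0.9
    c1: float = 1.5
    c2: float = 1.5
    r_mode: str = "fixed"  # "fixed" (r1=r2=r_value) or "random"
    r_value: float = 0.85
    v_max: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.w_min <= self.w_max:
            raise ValueError("need 0 < w_min <= w_max")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.r_mode not in ("fixed", "random"):
            raise ValueError("r_mode must be 'fixed' or 'random'")


@dataclass
class RdoConfig:
    """Red-deer parameters; defaults are the published operating point
    (population 100, 12 males, alpha 0.9, beta 0.5, gamma 0.6, roar 0.23,
    fight 0.47, mating 0.78).  hinds = n_pop - n_males unless overridden."""

    n_pop: int = 100
    n_males: int = 12
    alpha: float = 0.9
    beta: float = 0.5
    gamma: float = 0.6
    roar_p: float = 0.23
    fight_p: float = 0.47
    mating_p: float = 0.78
    UL: float = 4.0
    LL: float = -4.0
    max_iter: int = 50
    patience: int | None = None
    n_hinds_override: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_males >= self.n_pop:
            raise ValueError("population must exceed the number of males")
        if self.LL >= self.UL:
            raise ValueError("need LL < UL")

    @property
    def n_hinds(self) -> int:
        if self.n_hinds_override is not None:
            return self.n_hinds_override
        return self.n_pop - self.n_males


# ---------------------------------------------------------------------------
# PSO
# ---------------------------------------------------------------------------

def inertia_weight(k: int, cfg: PsoConfig) -> float:
    """Linear inertia decay from w_max at k=0 to w_min at k=k_max."""
    if not 0 <= k <= cfg.k_max:
        raise ValueError("iteration index out of range")
    return cfg.w_max - (cfg.w_max - cfg.w_min) * k / cfg.k_max


def pso_optimize(f, dim: int, cfg: PsoConfig | None = None, bounds=(-4.0, 4.0)):
    """Maximise ``f`` over a ``dim``-dimensional box with a particle swarm.

    Returns (best position, best score, trace) where trace[k] is the
    global-best score after iteration k (non-decreasing by construction).
    """
    cfg = cfg or PsoConfig()
    if dim < 1:
        raise ValueError("dim must be >= 1")
    lo, hi = bounds
    rng = np.random.default_rng(cfg.seed)
    P = rng.uniform(lo, hi, size=(cfg.n_particles, dim))
    V = rng.uniform(-abs(hi - lo) / 4, abs(hi - lo) / 4, size=P.shape)
    scores = np.array([float(f(p)) for p in P])
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite fitness at initialisation")
    pbest = P.copy()
    pbest_s = scores.copy()
    g = int(np.argmax(pbest_s))
    gbest, gbest_s = pbest[g].copy(), float(pbest_s[g])
    trace = []
    for k in range(cfg.k_max):
        w = inertia_weight(k, cfg)
        if cfg.r_mode == "fixed":
            r1 = r2 = cfg.r_value
        else:
            r1 = rng.uniform(size=P.shape)
            r2 = rng.uniform(size=P.shape)
        V = w * V + cfg.c1 * r1 * (pbest - P) + cfg.c2 * r2 * (gbest - P)
        np.clip(V, -cfg.v_max, cfg.v_max, out=V)
        P = np.clip(P + V, lo, hi)
        scores = np.array([float(f(p)) for p in P])
        if not np.all(np.isfinite(scores)):
            raise ValueError(f"non-finite fitness at iteration {k}")
        upd = scores > pbest_s
        pbest[upd] = P[upd]
        pbest_s[upd] = scores[upd]
        g = int(np.argmax(pbest_s))
        if pbest_s[g] > gbest_s:
            gbest, gbest_s = pbest[g].copy(), float(pbest_s[g])
        trace.append(gbest_s)
    return gbest, gbest_s, np.asarray(trace)


def position_to_mask(p) -> np.ndarray:
    """Decode a continuous position to a boolean keep mask.

    Feature i is kept iff sigmoid(p_i) > 0.5 (i.e. p_i > 0); if nothing
    passes, the single highest-sigmoid feature is kept as a rescue.
    """
    p = np.asarray(p, dtype=float)
    keep = p > 0
    if not keep.any():
        keep = np.zeros_like(keep)
        keep[int(np.argmax(p))] = True
    return keep


# ---------------------------------------------------------------------------
# RDO building blocks
# ---------------------------------------------------------------------------

def roaring_update(male, f, LL, UL, rng):
    """Local random move of a male, accepted only if fitness improves.

    The magnitude factor a2 and the sign factor a3 are scalar uniform
    draws; the attenuation a1 is drawn per coordinate so the step
    explores directions beyond the all-ones diagonal while small-step
    candidates stay likely.
    """
    male = np.asarray(male, dtype=float)
    a1 = rng.uniform(size=male.shape)
    a2 = rng.uniform()
    a3 = rng.uniform()
    step = a1 * ((UL - LL) * a2 + LL)
    cand = male + step if a3 >= 0.5 else male - step
    cand = np.clip(cand, LL, UL)
    if float(f(cand)) > float(f(male)):
        return cand
    return male


def fight_update(com, stag, f, LL, UL, rng):
    """Commander/stag contest: best of the pair and two blend points wins."""
    com = np.asarray(com, dtype=float)
    stag = np.asarray(stag, dtype=float)
    b1 = rng.uniform(size=com.shape)  # per-coordinate, like roaring's a1
    b2 = rng.uniform()
    shift = b1 * ((UL - LL) * b2 + LL)
    mid = (com + stag) / 2.0
    new1 = np.clip(mid + shift, LL, UL)
    new2 = np.clip(mid - shift, LL, UL)
    cands = [com, stag, new1, new2]
    scores = [float(f(c)) for c in cands]
    return cands[int(np.argmax(scores))].copy()


def harem_allocation(fitnesses, n_hinds: int) -> np.ndarray:
    """Hind counts per commander, proportional to fitness share.

    ``round(P_n * n_hinds)`` with a largest-remainder correction so the
    counts sum exactly to ``n_hinds``.  All-zero fitness splits equally.
    """
    fit = np.asarray(fitnesses, dtype=float)
    if np.any(fit < 0):
        fit = fit - fit.min()  # shift to non-negative shares
    total = fit.sum()
    if total <= 0:
        shares = np.full(len(fit), 1.0 / len(fit))
    else:
        shares = fit / total
    raw = shares * n_hinds
    counts = np.round(raw).astype(int)
    diff = n_hinds - counts.sum()
    if diff != 0:
        rem = raw - np.floor(raw)
        order = np.argsort(-rem if diff > 0 else rem)
        for i in range(abs(diff)):
            counts[order[i % len(counts)]] += 1 if diff > 0 else -1
    counts = np.clip(counts, 0, None)
    # clipping can only have removed counts; re-add to the largest share
    while counts.sum() < n_hinds:
        counts[int(np.argmax(shares))] += 1
    while counts.sum() > n_hinds:
        pos = np.nonzero(counts > 0)[0]
        counts[pos[int(np.argmin(shares[pos]))]] -= 1
    return counts


def offspring_update(parent_a, parent_b, LL, UL, rng):
    """Offspring = midpoint of the parents plus uniform blend noise."""
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    c = rng.uniform()
    return np.clip((a + b) / 2.0 + (UL - LL) * c, LL, UL)


def rdo_optimize(f, dim: int, cfg: RdoConfig | None = None):
    """Maximise ``f`` over [LL, UL]^dim with the red deer algorithm.

    Generational loop: rank -> males/hinds split -> commanders/stags by
    gamma -> roaring -> fights -> harems -> matings (alpha share of own
    harem, beta share of another harem, stags with the nearest hind) ->
    elitist survivor selection back to n_pop.  Stops at max_iter or when
    the best score stalls for ``patience`` generations.

    Returns (best position, best score, trace).
    """
    cfg = cfg or RdoConfig()
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    LL, UL = cfg.LL, cfg.UL
    pop = rng.uniform(LL, UL, size=(cfg.n_pop, dim))
    scores = np.array([float(f(p)) for p in pop])
    best_pos = pop[int(np.argmax(scores))].copy()
    best_s = float(scores.max())
    trace = []
    stall = 0
    for gen in range(cfg.max_iter):
        order = np.argsort(-scores)
        pop, scores = pop[order], scores[order]
        males = [pop[i].copy() for i in range(cfg.n_males)]
        hinds = [pop[i].copy() for i in range(cfg.n_males, cfg.n_pop)]
        # roaring
        for i in range(len(males)):
            if rng.uniform() < cfg.roar_p:
                males[i] = roaring_update(males[i], f, LL, UL, rng)
        male_scores = np.array([float(f(m)) for m in males])
        m_order = np.argsort(-male_scores)
        males = [males[i] for i in m_order]
        n_com = max(1, int(round(cfg.gamma * len(males))))
        commanders = males[:n_com]
        stags = males[n_com:]
        # fights
        for i in range(len(commanders)):
            if stags and rng.uniform() < cfg.fight_p:
                stag = stags[rng.integers(len(stags))]
                commanders[i] = fight_update(commanders[i], stag, f, LL, UL, rng)
        com_scores = np.array([float(f(c)) for c in commanders])
        # harems
        counts = harem_allocation(com_scores, len(hinds))
        hind_order = rng.permutation(len(hinds))
        harems: list[list[int]] = []
        pos = 0
        for c in counts:
            harems.append(list(hind_order[pos : pos + c]))
            pos += c
        # matings
        offspring = []
        for ci, com in enumerate(commanders):
            own = harems[ci]
            n_mate = int(round(cfg.alpha * len(own)))
            for hi in rng.permutation(own)[:n_mate]:
                if rng.uniform() < cfg.mating_p:
                    offspring.append(offspring_update(com, hinds[hi], LL, UL, rng))
            others = [h for cj, hs in enumerate(harems) if cj != ci for h in hs]
            n_other = int(round(cfg.beta * len(others)))
            if n_other and others:
                picks = rng.permutation(len(others))[:n_other]
                for k in picks:
                    if rng.uniform() < cfg.mating_p:
                        offspring.append(
                            offspring_update(com, hinds[others[k]], LL, UL, rng)
                        )
        for stag in stags:
            if hinds and rng.uniform() < cfg.mating_p:
                d = [float(np.sum((stag - h) ** 2)) for h in hinds]
                offspring.append(
                    offspring_update(stag, hinds[int(np.argmin(d))], LL, UL, rng)
                )
        # survivor selection: keep males, refill from hinds + offspring
        keep = males
        cand = hinds + offspring
        cand_scores = np.array([float(f(c)) for c in cand]) if cand else np.array([])
        need = cfg.n_pop - len(keep)
        if len(cand) > need:
            sel = np.argsort(-cand_scores)[:need]
            cand = [cand[i] for i in sel]
        while len(cand) < need:  # pad with fresh random deer
            cand.append(rng.uniform(LL, UL, size=dim))
        pop = np.vstack(keep + cand)
        scores = np.array([float(f(p)) for p in pop])
        gen_best = float(scores.max())
        if gen_best > best_s:
            best_s = gen_best
            best_pos = pop[int(np.argmax(scores))].copy()
            stall = 0
        else:
            stall += 1
        trace.append(best_s)
        if cfg.patience is not None and stall >= cfg.patience:
            break
    return best_pos, best_s, np.asarray(trace)


# ---------------------------------------------------------------------------
# Wrapper feature selection
# ---------------------------------------------------------------------------

def make_mask_fitness(X, y, sparsity_penalty: float = 0.01, n_folds: int = 3, seed: int = 0):
    """Wrapper fitness: stratified CV accuracy of KNN(k=5) on masked
    features, minus ``sparsity_penalty * (n_selected / d)``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    d = X.shape[1]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    def fitness(position):
        keep = position_to_mask(position)
        Xm = X[:, keep]
        accs = []
        for tr, te in folds:
            clf = KNeighborsClassifier(n_neighbors=min(5, len(tr)))
            clf.fit(Xm[tr], y[tr])
            accs.append(float(np.mean(clf.predict(Xm[te]) == y[te])))
        return float(np.mean(accs)) - sparsity_penalty * keep.sum() / d

    return fitness


def select_features(
    X,
    y,
    method: str = "rdo",
    cfg=None,
    sparsity_penalty: float = 0.01,
    n_folds: int = 3,
    seed: int = 0,
):
    """Run the PSO or RDO wrapper on a labelled feature matrix.

    Returns a dict with ``mask`` (boolean keep vector), ``n_selected``,
    ``best_score`` and ``trace``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    d = X.shape[1]
    fitness = make_mask_fitness(X, y, sparsity_penalty, n_folds, seed)
    if method == "pso":
        cfg = cfg or PsoConfig(n_particles=30, k_max=150, c1=2.0, c2=2.0,
                               r_mode="random", seed=seed)
        pos, score, trace = pso_optimize(fitness, d, cfg)
    elif method == "rdo":
        cfg = cfg or RdoConfig(n_pop=40, n_males=8, max_iter=40, seed=seed)
        pos, score, trace = rdo_optimize(fitness, d, cfg)
    else:
        raise ValueError(f"unknown method {method!r}")
    mask = position_to_mask(pos)
    return {
        "mask": mask,
        "n_selected": int(mask.sum()),
        "best_score": float(score),
        "trace": trace,
    }


# ---------------------------------------------------------------------------
# Entropy diagnostics
# ---------------------------------------------------------------------------

def approximate_entropy(x, n: int = 2, r_tol: float | None = None) -> float:
    """Approximate entropy of a series: ln(B^n / B^{n+1}).

    B^n is the mean over templates of length n of the fraction of
    templates within Chebyshev distance r of each (self-matches included,
    so the estimate is finite and non-negative).  ``r_tol`` defaults to
    0.2 times the series standard deviation.
    """
    x = np.asarray(x, dtype=float).ravel()
    M = x.size
    if M <= n + 1:
        raise ValueError("series too short")
    if r_tol is None:
        r_tol = 0.2 * float(np.std(x))
    if r_tol <= 0:
        r_tol = 1e-12  # constant series: every template still self-matches

    def _phi(m):
        n_t = M - m + 1
        tmpl = np.lib.stride_tricks.sliding_window_view(x, m)
        # Chebyshev distances between all template pairs
        d = np.abs(tmpl[:, None, :] - tmpl[None, :, :]).max(axis=2)
        frac = (d <= r_tol).sum(axis=1) / n_t
        return float(np.mean(np.log(frac)))

    return max(0.0, _phi(n) - _phi(n + 1))


def shannon_entropy(p) -> float:
    """Shannon entropy -sum p ln p of a probability vector (0 ln 0 = 0)."""
    p = np.asarray(p, dtype=float).ravel()
    if np.any(p < 0):
        raise ValueError("negative probability")
    s = p.sum()
    if not np.isclose(s, 1.0, atol=1e-6):
        raise ValueError("probabilities must sum to 1")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def values_to_probabilities(x, bins: int = 16) -> np.ndarray:
    """Histogram a value series into ``bins`` equal-width probability bins."""
    x = np.asarray(x, dtype=float).ravel()
    counts, _ = np.histogram(x, bins=bins)
    return counts / counts.sum()


def fuzzy_entropy(x, n: int = 2, width: float = 0.25) -> float:
    """Fuzzy entropy ln(phi^n / phi^{n+1}) with Gaussian-decay membership.

    phi^n averages the pairwise memberships exp(-d^2 / width) over
    mean-subtracted templates of length n, excluding self-pairs; d is the
    Chebyshev distance.
    """
    x = np.asarray(x, dtype=float).ravel()
    M = x.size
    if M <= n + 1:
        raise ValueError("series too short")
    if width <= 0:
        raise ValueError("width must be positive")

    def _phi(m):
        n_t = M - m
        tmpl = np.lib.stride_tricks.sliding_window_view(x, m)[:n_t]
        tmpl = tmpl - tmpl.mean(axis=1, keepdims=True)
        d = np.abs(tmpl[:, None, :] - tmpl[None, :, :]).max(axis=2)
        memb = np.exp(-(d**2) / width)
        np.fill_diagonal(memb, 0.0)
        return float(memb.sum() / (n_t * (n_t - 1)))

    p_n, p_n1 = _phi(n), _phi(n + 1)
    if p_n1 <= 0:
        return float("inf")
    return max(0.0, float(np.log(p_n / p_n1)))
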