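# Methods

`histofuse` implements a classical-plus-deep pipeline for two-class
histopathology tile classification (benign vs adenocarcinoma):
preprocessing, entropy-guided superpixel segmentation, weighted fusion of
multi-backbone deep features, metaheuristic wrapper feature selection,
a bank of formula-level classifiers, and stratified K-fold evaluation.
This note records the models, the parameters that matter, the numerical
choices made where the design was open, and what the synthetic test bed
does and does not demonstrate.

## Preprocessing

Tiles are converted to grayscale with BT.601 luma weights
(0.299, 0.587, 0.114), resized bilinearly to the working resolution
(224×224 by convention; the test bed uses 64×64), and denoised with an
adaptive fuzzy filter: each pixel becomes the membership-weighted mean of
its window, the membership being a Gaussian
`exp(-(I_n - I_c)^2 / (2 sigma^2))` in the "similar to the centre" fuzzy
set. Defaults: window 3, sigma 30 intensity units — sigma comparable to
the noise scale averages noise within regions while giving near-zero
weight across a nucleus/stroma edge (intensity gap ≈ 120). The filter is
a stand-in design: "adaptive fuzzy filter" names a family rather than a
formula, and this is the simplest member with a testable contract
(idempotent on constants, range-bounded, edge-preserving). All border
handling in the package uses reflect padding to avoid halo artifacts.

## Entropy-guided SLIC segmentation

1. **Kapur multilevel thresholding.** The 256-bin intensity histogram is
   cut at k thresholds maximising the summed Shannon entropies of the
   k+1 segments, `phi = sum_seg [log P_seg - (sum p log p)/P_seg]`.
   For k ≤ 2 the search is exhaustive (vectorised over all tuples, so it
   is exact); for k ≥ 3 it is coordinate ascent from quantile
   initialisation, which keeps phi non-decreasing per sweep but is only
   locally optimal. Ties break to the lexicographically smallest tuple.
   Default k = 2.
2. **Contrast enhancement.** Each intensity interval between thresholds
   (bounds `[1, t1, ..., tk, 255]`) is mapped onto an equal share of
   [1, 255] by power curves `f(x) = a x^r + b` (default r = 2) fitted to
   interval endpoints. Each interval is split at its probability-weighted
   centroid X_m, which maps to the target midpoint Y_m — giving the
   S-shaped transfer with its turning point at the interval's mass
   centre. The map is piecewise monotone with matching endpoints, hence
   globally monotone; intensities are clipped into the curve domain
   x ≥ 1 first. If an interval carries no mass or the centroid sits at an
   endpoint, a single curve spans the interval.
3. **Seeding.** Centres go on a regular grid with spacing
   `S = sqrt(N/M)` for M target superpixels (the square root is forced by
   each superpixel containing N/M pixels in 2-D), then move to the
   minimum-gradient position in their 3×3 neighbourhood (ties keep the
   original position).
4. **Clustering.** Localised k-means in (x, y, gs) with the distance
   `d' = sqrt(d_spatial^2 + alpha * d_gray^2)` evaluated inside a
   *circular* window of radius S around each centre — cells are round,
   so a round search window fits them. `alpha` defaults to `(S/m)^2`
   with compactness m = 20 (range 1–40), which makes the grayscale and
   spatial terms commensurate; the classic SLIC normalisation
   `sqrt(d_g^2 + (d_s/S)^2 m^2)` is available via
   `distance_mode="standard"`, and `alpha_override` pins alpha directly
   (`alpha_override=0` gives the pure spatial Voronoi limit used in
   tests). Ties in the assignment go to the lower centre label. Corner
   pixels outside every circular window are assigned to the globally
   nearest centre. Convergence: mean centre displacement < 0.5 px or 10
   iterations, whichever first.
5. **Merging.** Connected fragments smaller than `floor(S^2/4)` pixels
   are absorbed into the adjacent segment sharing the longest boundary
   (4-connectivity; ties to the smaller label), repeated until no
   undersized fragment remains; labels are then compacted to 0..n-1.
6. **ROI.** Superpixels whose mean enhanced intensity falls below the
   global Otsu threshold are flagged as nuclei-dense (hematoxylin stains
   nuclei dark). This is a pragmatic reading of "segmentation result";
   nothing downstream depends on it being the only possible reading.

## DWAFF feature fusion

Three backbone feature matrices (RN-50/101/152 by convention; any
conformable triplet) are fused per entry. Faithful mode:
`(w1 f152 + w2 f101 + w3 f50)/3 + mean_class(j)` with scalar per-class
offsets equal to the backbone-averaged grand means — this is the form
used for training data, and the /3 divisor is kept because that is the
form the downstream features are defined by (a `divide_by_three` switch
exposes the divisor-free variant). Leak-free mode drops the offset and
the /3, leaving a plain convex combination that needs no labels and is
the default at inference, since the offset requires knowing the class of
the row it is added to. Inside cross-validation the offsets are
estimated from training folds only.

Weights live on the simplex; the operating point is
(w1, w2, w3) = (0.45, 0.35, 0.20). The weight search scores every grid
point (default step 0.05 — the operating point does not exist on a 0.1
grid) by mean K-fold accuracy of a KNN(k=5) reference classifier on the
fused features, with ties broken to larger w1 then w2, matching the
backbone quality ranking RN-152 > RN-101 > RN-50.

## Wrapper feature selection

A candidate subset is encoded as a continuous vector, one coordinate per
feature, decoded by `sigmoid(p_i) > 0.5` (argmax rescue if the mask would
be empty). Fitness = mean stratified 3-fold accuracy of KNN(k=5) on the
masked features minus `0.01 * n_selected/d`. The penalty is deliberately
small: it breaks ties between equally accurate masks without ever paying
a measurable accuracy cost for an informative feature.

**PSO.** Velocity rule `q <- w q + c1 r1 (pbest-p) + c2 r2 (gbest-p)`
with the inertia weight decaying linearly from 0.9 to 0.45 over the run.
`r_mode="fixed"` (r1 = r2 = 0.85) reproduces the stated configuration;
`r_mode="random"` uses per-step uniform draws and is the default inside
`select_features`, where the extra stochasticity helps the
high-dimensional subset search. Wrapper defaults: 30 particles, 150
iterations, c1 = c2 = 2.0, velocities clamped to ±4.

**RDO.** Generational loop: rank population (100 by default, 12 males;
hinds = population − males, since the generational bookkeeping must
conserve the population), split males into commanders (gamma = 0.6
share) and stags, roar (local move kept only on improvement, gated per
male by roar probability 0.23), commander-stag fights (best of the pair
and two blend points, gated at 0.47), harems allotted proportionally to
commander fitness with largest-remainder rounding so counts sum exactly,
matings (alpha = 0.9 share of own harem, beta = 0.5 of other harems,
stags with the nearest hind, each gated at 0.78), offspring =
parent midpoint + (UL−LL)·c with c ~ U(0,1), and elitist survivor
selection back to the fixed population size. One numerical choice
matters: the uniform attenuation factors in the roar and fight moves
(a1, b1) are drawn per coordinate while the magnitude and sign factors
(a2, a3, b2, c) stay scalar. With every factor scalar, all moves lie
along the all-ones diagonal and the search provably stalls on the sphere
benchmark once the incumbent's coordinates sum to ≈ 0 (observed plateau
at f ≈ 0.07 regardless of generations); the per-coordinate attenuation
restores isotropic exploration while leaving the printed update formulas
and their fixed-draw hand evaluations intact. Wrapper defaults:
population 40, 8 males, 40 generations.

Elitism makes both optimizers' best-so-far traces monotone, and all
randomness flows from one seeded generator per run.

**Entropy diagnostics.** Approximate entropy (template length n = 2,
tolerance 0.2·SD, Chebyshev distance, self-matches included so the
estimate stays finite), Shannon entropy (natural log, 0·log 0 = 0, with
a 16-bin equal-width histogram rule for raw value series), and fuzzy
entropy (mean-subtracted templates, Gaussian membership
`exp(-d^2/width)` with width 0.25, self-pairs excluded). Negative
estimates arising from finite-sample fluctuation are clamped to 0 for
AE/FE, whose population values are non-negative.

## Classifiers

* **SDC** (softmax discriminant): assign to the class maximising
  `logsumexp(-lambda ||v - v_n^j||^2)` over the class's training
  samples; lambda = 0.458. Large lambda reduces to 1-NN; small lambda to
  a class-aggregate distance. Ties go to class 0.
* **BLDC**: Bayesian ridge regression of bias-augmented features onto
  class targets (0.15, 0.85). Posterior covariance
  `H = (beta V V^T + R'(alpha))^{-1}` with `R' = diag(alpha,...,alpha,
  eps)` (the bias is essentially unregularised, eps = 1e-6 by default);
  posterior mean `U = beta H V a`, computed with `numpy.linalg.solve`
  rather than an explicit inverse. Predictions: mean `v^T U`, variance
  `1/beta + v^T H v` (always > 1/beta for the augmented vector), class =
  positive iff the mean exceeds the target midpoint. alpha and beta are
  fixed configuration values (defaults 1.0) — no evidence maximisation
  loop is implied by the model as stated. The targets are placed with
  this classifier because regression-to-targets is the only model here
  they are meaningful for.
* **MLP**: one sigmoid hidden layer (default 20 units — the hidden size
  is otherwise unconstrained), sigmoid output, squared-error cost,
  full-batch gradient descent with mean-normalised gradients, learning
  rate 0.45, default epoch budget 15 (the protocol treats longer
  training as an overfitting risk; the budget is configurable, and the
  XOR check uses a larger one since four points cannot overfit).
  Levenberg–Marquardt training is deliberately out of scope; the cost
  function is what is honoured.
* **Baselines** delegate to scikit-learn: SVM-RBF with
  `gamma = 1/(2·98^2)` (kernel bandwidth sigma = 98) and the
  support-vector coefficient 1.8 mapped to C — the stated bias term has
  no free counterpart and is absorbed by the fitted intercept; KNN k = 5
  Euclidean distance-weighted; RF 150 trees, depth 15; DT depth 14 with
  entropy splits.

## Evaluation

Benign (label 0) is the *positive* class: TP = benign called benign,
FP = adenocarcinoma called benign. Folds are stratified (class balance
per fold is what keeps K = 2 stable) and seed-shuffled. Metrics:
accuracy, error rate (their sum is exactly 100), F1 = 2TP/(2TP+FP+FN)
(identical to the Dice coefficient), MCC, Jaccard = TP/(TP+FP+FN)
(algebraically J = F1/(2−F1) on proportions), G-mean =
sqrt(sensitivity·specificity), and Cohen's kappa with chance agreement
from the marginal products. A metric whose denominator vanishes is
reported as 0 and named in an `undefined` flag — explicit, testable
degenerate behaviour. `cross_validate` re-fits the entire pipeline per
fold, so standardisation, offsets, weight search and feature selection
never see held-out rows.

## Synthetic test bed

`synthfix.make_image` draws tiles of pale stroma (mean 200) with dark
elliptical nuclei (mean 80) whose boundaries carry a sinusoidal
perturbation of relative amplitude 0.3·irregularity, plus Gaussian
noise and a faint low-frequency texture. The class presets emulate
nuclear morphometry rather than stain load: both classes cover ≈ 20% of
the tile, but benign tiles have 5 large round nuclei (radius 9–14% of
the tile side, irregularity 0.15) while adenocarcinoma tiles have 10
smaller rough ones (6.5–10%, irregularity 0.5). Equalising the stained
area is deliberate: it removes the shortcut of classifying by global
darkness and forces object-level analysis, which is exactly what the
segmentation stage contributes.

`synthfix.make_feature_triplet` draws three correlated non-negative
matrices: shared and independent lognormal components mixed as
`sqrt(rho) Z + sqrt(1-rho) E_b` (default rho = 0.7), with the component
skewness inflated so the mixture hits the target pooled skewness
(default 5.5, the regime of pooled ReLU features), and a class shift
(default 1.0) planted on the informative columns. Defaults mirror the
emulated dataset scale (5000 per class × 2048 features); tests and the
acceptance script pass scaled-down specs — 30–50 rows per class and
60–100 features — chosen so every check runs on one CPU in minutes
while leaving the planted-recovery problems genuinely non-trivial.

The four-scenario experiment (`pipeline.run_experiment`) has no
pretrained backbone, so the "backbones" are three jittered copies of a
10-descriptor morphometric extractor (area fraction, object count, size
statistics, intensity moments, histogram entropy, edge and boundary
density) padded to 24 columns with uninformative lognormal noise that
mimics inactive deep channels. The RN-152-like copy carries the least
jitter (5% vs 10% and 20%), giving the weight search a real ranking to
find. On raw noisy tiles (noise sd 25) the dark-object mask is speckled
and object counts are unreliable; after fuzzy filtering, enhancement and
superpixel ROI extraction the counts and boundary densities become
clean, and wrapper selection then prunes the noise padding — which is
why mean CV accuracy orders none ≤ seg ≤ seg+selection on this bed.

**What passing does not show.** The generator has no stain variation,
no texture inside nuclei, no touching-cell clumps, no class overlap in
morphology; real tiles have all of these. Results on this bed validate
the machinery — exact thresholding, clustering descent, fusion
arithmetic, optimizer convergence and bookkeeping, leakage containment,
metric identities, and the qualitative value of segmentation and
selection — not clinical performance, and no accuracy obtained here is
comparable to numbers reported on real histopathology datasets.

## Degenerate inputs and tie-breaks

Near-constant images yield no feasible threshold; segmentation then
skips enhancement rather than failing. Empty clusters keep their centre.
Equal assignment distances go to the lower label; equal merge boundary
lengths to the smaller label; equal entropy to the smallest threshold
tuple; equal weight-search scores to larger w1 then w2; SDC ties to
class 0; BLDC means exactly at the midpoint to the negative class.

## Known limitations

The k ≥ 3 thresholding is locally optimal only. The ROI rule assumes
dark-on-light staining. The RDO mating bias (offspring noise is strictly
positive before clipping) is inherited from the update rule as printed;
survivor selection filters it but it wastes evaluations. `faithful`
fusion adds a label-dependent offset and is unusable on unlabeled data
by construction — the leak-free mode exists precisely for that. The MLP
is full-batch and first-order; it is a formula-level reference
implementation, not a performance-tuned network.
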