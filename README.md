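# histofuse

Superpixel-guided feature fusion and classification for two-class
histopathology tiles (benign vs adenocarcinoma), built so that every
stage is testable on synthetic data with no dataset download and no
pretrained network.

**Who it is for.** Researchers and engineers who want the classical
machinery around a deep-feature histopathology classifier — entropy-based
segmentation, multi-backbone feature fusion, metaheuristic feature
selection, formula-level classifiers, leakage-safe cross-validation — as
a reusable, seeded, unit-tested library rather than a monolithic script.

## What's inside

* **Entropy-guided SLIC** (`histofuse.slic_entropy`): Kapur
  maximum-entropy multilevel thresholding (exact for k ≤ 2), piecewise
  power-law contrast enhancement between thresholds, and a grayscale
  SLIC variant clustering pixels in (x, y, gs) with
  d′ = √(d²ₛ + α·d²_g) inside circular windows of radius S = √(N/M),
  followed by small-superpixel merging and ROI extraction.
* **DWAFF fusion** (`histofuse.fusion`): the deep-weighted
  averaging-based feature fusion of three backbone matrices,
  fused[i,j] = (w₁·f152 + w₂·f101 + w₃·f50)/3 + mean_class(j) in
  faithful mode, plain convex combination in leak-free mode; simplex
  grid search for the weights (operating point 0.45/0.35/0.20) scored by
  KNN cross-validation.
* **Selective feature pooling** (`histofuse.selector`): PSO (linearly
  decaying inertia 0.9→0.45) and the red deer algorithm (roaring,
  commander-stag fights, fitness-proportional harems, mating) as wrapper
  feature selectors over a sigmoid-decoded mask, plus approximate,
  Shannon and fuzzy entropy diagnostics.
* **Classifiers** (`histofuse.classify`): softmax discriminant
  (λ = 0.458), Bayesian linear discriminant (ridge posterior, predictive
  mean and variance, targets 0.15/0.85), a single-hidden-layer MLP
  trained on squared error, and scikit-learn-backed SVM-RBF / decision
  tree / random forest / KNN baselines behind one fit/predict contract.
* **Evaluation** (`histofuse.evaluate`): stratified K-fold
  (K ∈ {2, 4, 5, 8, 10}) with the clinical convention that *benign* is
  the positive class, and the seven-metric suite (accuracy, error rate,
  F1, MCC, Jaccard, G-mean, kappa).
* **Synthetic fixtures** (`histofuse.synthfix`): seeded generators for
  histology-like nucleus tiles with ground-truth masks and for
  correlated, skewed backbone feature triplets with planted class
  signal; benchmark fitness surfaces for the optimizers.
* **Pipeline + CLI** (`histofuse.pipeline`, `histofuse` console
  script): the four experimental scenarios — no segmentation /
  segmentation / +PSO selection / +RDO selection — end to end.

## Worked example

```python
import numpy as np
from histofuse import synthfix, imaging, slic_entropy, fusion, evaluate, pipeline

# segment a synthetic adenocarcinoma-like tile
spec = synthfix.image_spec_for_class(1, seed=0, size=(64, 64))
img, gt = synthfix.make_image(spec)
filt = imaging.adaptive_fuzzy_filter(img)
res = slic_entropy.segment(filt, slic_entropy.SlicConfig(M=25))
print("thresholds:", res["thresholds"])
print("superpixels:", res["labels"].max() + 1)
print("boundary recall:", round(evaluate.boundary_recall(gt, res["labels"]), 3))

# fuse a synthetic backbone triplet and cross-validate KNN on it
fspec = synthfix.SynthFeatureSpec(n_per_class=30, dim=60, n_informative=10,
                                  class_shift=1.5, seed=7)
f50, f101, f152, y = synthfix.make_feature_triplet(fspec)
fused = fusion.dwaff_fuse(f50, f101, f152)   # leak-free, weights (0.45, 0.35, 0.20)
cv = evaluate.cross_validate(
    lambda: pipeline.ScenarioPipeline("knn", None, seed=0), fused, y, K=5, seed=0)
print("fused KNN 5-fold accuracy: %.1f%% +/- %.1f"
      % (cv["mean"]["accuracy"], cv["sd"]["accuracy"]))
print("MCC %.3f  kappa %.3f" % (cv["mean"]["mcc"], cv["mean"]["kappa"]))
```

Output:

```
thresholds: [84, 192]
superpixels: 22
boundary recall: 0.965
fused KNN 5-fold accuracy: 95.0% +/- 4.6
MCC 0.907  kappa 0.900
```

The two entropy thresholds split the histogram into nucleus, stroma and
highlight strata; 25 requested superpixels merge down to 22, whose
boundaries recover 96.5% of the true nucleus outlines within 2 px. On
the feature side, the fused matrix classifies the planted two-class
structure at 95% mean 5-fold accuracy; MCC and kappa near 0.9 say the
agreement is far above chance.

The same pipeline from the shell:

```bash
histofuse run --scenario seg_rdo --classifier knn --k-folds 5 --seed 0 --out runs/demo
histofuse simulate --n-per-class 10 --size 64 --out fixtures/
histofuse segment fixtures/images/tile_0000.png --m 25 --out seg/
```

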