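"""Binary classifiers: SDC, BLDC, MLP, and delegated baselines.

SDC — softmax discriminant classifier.  A test vector v is assigned to
the class j maximising ``log sum_n exp(-lambda ||v - v_n^j||^2)`` over
that class's training samples.  Large lambda makes the nearest sample
dominate (1-NN behaviour); small lambda averages distances over the
class.  Default lambda 0.458.

BLDC — Bayesian linear discriminant classifier.  Ridge-regularised
Bayesian linear regression of bias-augmented features onto class targets
(t_neg, t_pos) = (0.15, 0.85).  The Gaussian weight posterior has
covariance ``H = (beta V V^T + R'(alpha))^-1`` and mean
``U = beta H V a``, where V stacks training vectors as columns and
R'(alpha) = diag(alpha, ..., alpha, eps) regularises the weights but not
the bias.  Predictions carry a mean ``mu = v^T U`` and a variance
``delta^2 = 1/beta + v^T H v``; the class is positive iff mu exceeds the
target midpoint.

MLP — one sigmoid hidden layer trained by full-batch gradient descent on
the squared-error cost ``F = 1/2 sum (target - output)^2``.

The SVM-RBF, decision-tree, random-forest and KNN baselines delegate to
scikit-learn behind the same fit/predict contract, configured with the
study's operating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "SdcClassifier",
    "sdc_fit_predict",
    "BldcModel",
    "BldcClassifier",
    "bldc_fit",
    "bldc_predict",
    "MlpClassifier",
    "mlp_train_predict",
    "baseline_classifier",
    "make_classifier",
]

DEFAULT_SDC_LAMBDA = 0.458
DEFAULT_BLDC_TARGETS = (0.15, 0.85)


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be 2-D with one label per row")
    return X, y


# ---------------------------------------------------------------------------
# SDC
# ---------------------------------------------------------------------------

class SdcClassifier:
    """Softmax discriminant classifier (distance-based, non-parametric)."""

    name = "sdc"

    def __init__(self, lam: float = DEFAULT_SDC_LAMBDA):
        if lam <= 0:
            raise ValueError("lambda must be positive")
        self.lam = lam
        self._classes = None
        self._samples = None

    def fit(self, X, y):
        X, y = _check_xy(X, y)
        self._classes = np.unique(y)
        if len(self._classes) < 2:
            raise ValueError("both classes must be present")
        self._samples = {c: X[y == c] for c in self._classes}
        return self

    def predict(self, X):
        if self._samples is None:
            raise RuntimeError("fit before predict")
        X = np.asarray(X, dtype=float)
        scores = np.empty((X.shape[0], len(self._classes)))
        for j, c in enumerate(self._classes):
            S = self._samples[c]
            d2 = ((X[:, None, :] - S[None, :, :]) ** 2).sum(axis=2)
            scores[:, j] = logsumexp(-self.lam * d2, axis=1)
        # ties go to the first (lowest) class label
        return self._classes[np.argmax(scores, axis=1)]


def sdc_fit_predict(X_train, y_train, X_test, lam: float = DEFAULT_SDC_LAMBDA):
    """One-shot SDC convenience wrapper."""
    return SdcClassifier(lam).fit(X_train, y_train).predict(X_test)


# ---------------------------------------------------------------------------
# BLDC
# ---------------------------------------------------------------------------

@dataclass
class BldcModel:
    """Fitted posterior of the Bayesian linear discriminant."""

    U: np.ndarray  # posterior mean weights, bias last
    H: np.ndarray  # posterior covariance
    beta: float
    targets: tuple[float, float]


def bldc_fit(
    X,
    y,
    beta: float = 1.0,
    alpha_reg: float = 1.0,
    epsilon_bias: float = 1e-6,
    targets: tuple[float, float] = DEFAULT_BLDC_TARGETS,
) -> BldcModel:
    """Fit the Gaussian weight posterior of the BLDC.

    Features are augmented with a trailing constant-1 bias coordinate;
    labels map to regression targets (t_neg for class 0, t_pos for class
    1).  Solves ``H = (beta V V^T + R'(alpha))^-1`` and
    ``U = beta H V a`` with a numerically stable linear solve.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    X, y = _check_xy(X, y)
    t_neg, t_pos = targets
    a = np.where(y == 0, t_neg, t_pos).astype(float)
    V = np.hstack([X, np.ones((X.shape[0], 1))]).T  # (d+1) x n, columns = samples
    d1 = V.shape[0]
    R = np.diag(np.concatenate([np.full(d1 - 1, alpha_reg), [epsilon_bias]]))
    A = beta * (V @ V.T) + R
    try:
        H = np.linalg.solve(A, np.eye(d1))
    except np.linalg.LinAlgError as e:
        raise ValueError(
            "singular posterior precision; use alpha_reg > 0 on "
            "rank-deficient data"
        ) from e
    U = beta * np.linalg.solve(A, V @ a)
    return BldcModel(U=U, H=H, beta=beta, targets=(t_neg, t_pos))


def bldc_predict(model: BldcModel, X):
    """Predict labels and per-sample predictive (mean, variance).

    mu = v^T U, delta^2 = 1/beta + v^T H v; positive class iff mu exceeds
    the target midpoint (tie -> negative class).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] + 1 != model.U.shape[0]:
        raise ValueError("feature dimension mismatch with fitted model")
    V = np.hstack([X, np.ones((X.shape[0], 1))])
    mu = V @ model.U
    var = 1.0 / model.beta + np.einsum("ij,jk,ik->i", V, model.H, V)
    mid = 0.5 * (model.targets[0] + model.targets[1])
    labels = (mu > mid).astype(int)
    return labels, mu, var


class BldcClassifier:
    """fit/predict wrapper around bldc_fit / bldc_predict."""

    name = "bldc"

    def __init__(self, beta=1.0, alpha_reg=1.0, epsilon_bias=1e-6,
                 targets=DEFAULT_BLDC_TARGETS):
        self.params = dict(beta=beta, alpha_reg=alpha_reg,
                           epsilon_bias=epsilon_bias, targets=targets)
        self.model = None

    def fit(self, X, y):
        self.model = bldc_fit(X, y, **self.params)
        return self

    def predict(self, X):
        if self.model is None:
            raise RuntimeError("fit before predict")
        return bldc_predict(self.model, X)[0]


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------

class MlpClassifier:
    """Single-hidden-layer sigmoid perceptron, squared-error cost,
    full-batch gradient descent.  Deterministic under a fixed seed.

    The default epoch budget is 15 (training past that risks
    overfitting on the target data); both ``epochs`` and the learning
    rate are configurable.
    """

    name = "mlp"

    def __init__(self, hidden: int = 20, lr: float = 0.45, epochs: int = 15,
                 seed: int = 0):
        if hidden < 1:
            raise ValueError("hidden size must be >= 1")
        self.hidden = hidden
        self.lr = lr
        self.epochs = epochs
        self.seed = seed
        self.loss_trace: list[float] = []
        self._W1 = self._b1 = self._W2 = self._b2 = None

    def _init(self, d):
        rng = np.random.default_rng(self.seed)
        self._W1 = rng.normal(0, 1.0 / np.sqrt(d), size=(d, self.hidden))
        self._b1 = np.zeros(self.hidden)
        self._W2 = rng.normal(0, 1.0 / np.sqrt(self.hidden), size=self.hidden)
        self._b2 = 0.0

    def _forward(self, X):
        Z = expit(X @ self._W1 + self._b1)
        out = expit(Z @ self._W2 + self._b2)
        return Z, out

    def fit(self, X, y):
        X, y = _check_xy(X, y)
        t = y.astype(float)
        self._init(X.shape[1])
        self.loss_trace = []
        n = X.shape[0]
        for _ in range(self.epochs):
            Z, out = self._forward(X)
            err = out - t
            loss = 0.5 * float(np.sum(err**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "MLP training diverged; lower the learning rate"
                )
            self.loss_trace.append(loss)
            d_out = err * out * (1 - out)
            gW2 = Z.T @ d_out / n
            gb2 = d_out.mean()
            d_hid = np.outer(d_out, self._W2) * Z * (1 - Z)
            gW1 = X.T @ d_hid / n
            gb1 = d_hid.mean(axis=0)
            self._W2 -= self.lr * gW2
            self._b2 -= self.lr * gb2
            self._W1 -= self.lr * gW1
            self._b1 -= self.lr * gb1
        return self

    def predict(self, X):
        if self._W1 is None:
            raise RuntimeError("fit before predict")
        X = np.asarray(X, dtype=float)
        _, out = self._forward(X)
        return (out > 0.5).astype(int)


def mlp_train_predict(X_train, y_train, X_test, hidden=20, lr=0.45,
                      epochs=15, seed=0):
    """One-shot MLP convenience wrapper; returns (labels, loss trace)."""
    clf = MlpClassifier(hidden=hidden, lr=lr, epochs=epochs, seed=seed)
    if epochs > 0:
        clf.fit(X_train, y_train)
    else:
        X, _ = _check_xy(X_train, y_train)
        clf._init(X.shape[1])
    return clf.predict(X_test), list(clf.loss_trace)


# ---------------------------------------------------------------------------
# Delegated baselines
# ---------------------------------------------------------------------------

def baseline_classifier(name: str, **overrides):
    """Delegated baseline with the study's operating parameters.

    SVM-RBF: kernel bandwidth sigma = 98 mapped to gamma = 1/(2 sigma^2);
    the support-vector coefficient 1.8 maps to the C-like regularisation
    strength (the printed bias term has no sklearn counterpart and is
    absorbed by the fitted intercept).  KNN: k = 5, Euclidean,
    distance-weighted.  RF: 150 trees, depth 15.  DT: depth 14, entropy
    splits.
    """
    name = name.lower()
    if name == "svm":
        sigma = overrides.pop("sigma", 98.0)
        C = overrides.pop("C", 1.8)
        return SVC(kernel="rbf", gamma=1.0 / (2.0 * sigma**2), C=C, **overrides)
    if name == "knn":
        k = overrides.pop("k", 5)
        return KNeighborsClassifier(
            n_neighbors=k, metric="euclidean", weights="distance", **overrides
        )
    if name == "rf":
        return RandomForestClassifier(
            n_estimators=overrides.pop("n_trees", 150),
            max_depth=overrides.pop("max_depth", 15),
            random_state=overrides.pop("seed", 0),
            **overrides,
        )
    if name == "dt":
        return DecisionTreeClassifier(
            max_depth=overrides.pop("max_depth", 14),
            criterion=overrides.pop("criterion", "entropy"),
            random_state=overrides.pop("seed", 0),
            **overrides,
        )
    raise ValueError(f"unknown baseline {name!r}")


def make_classifier(name: str, seed: int = 0, **overrides):
    """Uniform factory over the full classifier bank."""
    name = name.lower()
    if name == "sdc":
        return SdcClassifier(**overrides)
    if name == "bldc":
        return BldcClassifier(**overrides)
    if name == "mlp":
        overrides.setdefault("seed", seed)
        return MlpClassifier(**overrides)
    if name in ("svm", "dt", "rf", "knn"):
        if name in ("dt", "rf"):
            overrides.setdefault("seed", seed)
        return baseline_classifier(name, **overrides)
    raise ValueError(f"unknown classifier {name!r}")
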