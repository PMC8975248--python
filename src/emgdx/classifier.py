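"""Three-layer perceptron (input → N_h hidden → 3 output) trained by
full-batch nonlinear conjugate gradient with Polak-Ribière updates.

The network uses a tanh hidden layer and logistic-sigmoid outputs, and
minimizes the sum of squared errors against one-hot class targets
([1 0 0], [0 1 0], [0 0 1] in the fixed order healthy, myopathy,
neuropathy).  One "epoch" is one conjugate-gradient iteration over the
full batch; an Armijo backtracking line search guarantees the loss is
non-increasing across accepted steps.  Everything (weight init, the
line search, hold-out splits) is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .features import FeatureVector
from .simulate import CLASSES

DEFAULT_GRID_NH = tuple(range(5, 51, 5))
DEFAULT_GRID_NE = tuple(range(50, 501, 50))


@dataclass(frozen=True)
class TrainingConfig:
    n_hidden: int = 25
    n_epochs: int = 300
    seed: int = 0
    standardize: bool = True

    def __post_init__(self):
        if self.n_hidden < 1 or self.n_epochs < 1:
            raise ValueError("n_hidden and n_epochs must be >= 1")


@dataclass
class MlpModel:
    w1: np.ndarray  # (n_features, n_hidden)
    b1: np.ndarray
    w2: np.ndarray  # (n_hidden, n_classes)
    b2: np.ndarray
    mu: np.ndarray  # per-feature standardization, learned on training data only
    sd: np.ndarray
    classes: tuple[str, ...] = CLASSES
    final_loss: float = np.nan

    @property
    def n_features(self) -> int:
        return self.w1.shape[0]


def _coerce_features(features, labels=None) -> tuple[np.ndarray, np.ndarray]:
    """Accept either a list of FeatureVector or a feature matrix (+labels)."""
    if len(features) and isinstance(features[0], FeatureVector):
        X = np.vstack([fv.fused for fv in features])
        y = np.asarray([fv.label for fv in features]) if labels is None else np.asarray(labels)
    else:
        X = np.asarray(features, dtype=float)
        y = np.asarray(labels) if labels is not None else np.full(len(X), "unknown")
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain NaN or infinite values")
    return X, y


def _one_hot(y: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    try:
        cols = np.asarray([index[v] for v in y])
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} outside the class set {tuple(classes)}") from None
    t = np.zeros((len(y), len(classes)))
    t[np.arange(len(y)), cols] = 1.0
    return t


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(theta, shapes, X):
    w1, b1, w2, b2 = _unpack(theta, shapes)
    hidden = np.tanh(X @ w1 + b1)
    return _sigmoid(hidden @ w2 + b2), hidden


def _pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def _unpack(theta, shapes):
    (d, h), c = shapes
    i = 0
    w1 = theta[i : i + d * h].reshape(d, h); i += d * h
    b1 = theta[i : i + h]; i += h
    w2 = theta[i : i + h * c].reshape(h, c); i += h * c
    b2 = theta[i : i + c]
    return w1, b1, w2, b2


def _loss_grad(theta, shapes, X, T):
    w1, b1, w2, b2 = _unpack(theta, shapes)
    hidden = np.tanh(X @ w1 + b1)
    out = _sigmoid(hidden @ w2 + b2)
    err = out - T
    loss = float(np.sum(err**2))
    d_out = 2.0 * err * out * (1.0 - out)
    g_w2 = hidden.T @ d_out
    g_b2 = d_out.sum(axis=0)
    d_hid = (d_out @ w2.T) * (1.0 - hidden**2)
    g_w1 = X.T @ d_hid
    g_b1 = d_hid.sum(axis=0)
    return loss, _pack(g_w1, g_b1, g_w2, g_b2)


def _loss(theta, shapes, X, T) -> float:
    out, _ = _forward(theta, shapes, X)
    return float(np.sum((out - T) ** 2))


def _cg_minimize(theta, shapes, X, T, n_iter: int) -> tuple[np.ndarray, float]:
    """Polak-Ribière (PR+) nonlinear CG with Armijo backtracking."""
    loss, g = _loss_grad(theta, shapes, X, T)
    d = -g
    alpha = 1.0 / max(1.0, np.linalg.norm(g))
    for _ in range(n_iter):
        slope = g @ d
        if slope >= 0:  # not a descent direction: restart on steepest descent
            d = -g
            slope = g @ d
            if slope >= 0:
                break  # gradient numerically zero
        a = alpha * 2.0  # mild expansion of the last accepted step
        accepted = False
        for _bt in range(40):
            new_theta = theta + a * d
            new_loss = _loss(new_theta, shapes, X, T)
            if new_loss <= loss + 1e-4 * a * slope:
                accepted = True
                break
            a *= 0.5
        if not accepted:
            if np.allclose(d, -g):
                break  # cannot make progress even along steepest descent
            d = -g
            continue
        theta = new_theta
        alpha = a
        new_loss2, g_new = _loss_grad(theta, shapes, X, T)
        loss = new_loss2
        beta = max(0.0, g_new @ (g_new - g) / max(g @ g, np.finfo(float).tiny))
        d = -g_new + beta * d
        g = g_new
    return theta, loss


def train_mlpnn(features, config: TrainingConfig = TrainingConfig(), labels=None) -> MlpModel:
    """Fit the MLP on labeled feature vectors.

    Features are standardized with training-set statistics only (applied
    again at prediction time), weights start uniform in
    ±1/sqrt(fan_in), and training runs at most ``n_epochs`` CG
    iterations.  Requires at least two classes in the training labels.
    """
    X, y = _coerce_features(features, labels)
    if len(set(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    unknown = set(y) - set(CLASSES)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} outside the class set {CLASSES}")

    if config.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        if np.any(sd == 0):
            warnings.warn("zero-variance features; their scale is left at 1")
            sd = np.where(sd == 0, 1.0, sd)
    else:
        mu = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    Xs = (X - mu) / sd
    T = _one_hot(y, CLASSES)

    d = X.shape[1]
    h = config.n_hidden
    c = len(CLASSES)
    rng = np.random.default_rng(config.seed)
    w1 = rng.uniform(-1, 1, size=(d, h)) / np.sqrt(d)
    b1 = rng.uniform(-1, 1, size=h) / np.sqrt(d)
    w2 = rng.uniform(-1, 1, size=(h, c)) / np.sqrt(h)
    b2 = rng.uniform(-1, 1, size=c) / np.sqrt(h)
    shapes = ((d, h), c)
    theta, final_loss = _cg_minimize(_pack(w1, b1, w2, b2), shapes, Xs, T, config.n_epochs)
    w1, b1, w2, b2 = (arr.copy() for arr in _unpack(theta, shapes))
    return MlpModel(w1=w1, b1=b1, w2=w2, b2=b2, mu=mu, sd=sd, final_loss=final_loss)


def predict(model: MlpModel, features, labels=None) -> list[tuple[str, np.ndarray]]:
    """Class label and the 3 output scores for each feature vector.

    The label is the argmax of the scores; exact ties resolve to the
    first class in the fixed order (healthy < myopathy < neuropathy).
    """
    X, _ = _coerce_features(features, labels)
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
    Xs = (X - model.mu) / model.sd
    hidden = np.tanh(Xs @ model.w1 + model.b1)
    scores = _sigmoid(hidden @ model.w2 + model.b2)
    picks = np.argmax(scores, axis=1)  # argmax returns the first maximum
    return [(model.classes[p], scores[i]) for i, p in enumerate(picks)]


def predict_labels(model: MlpModel, X) -> np.ndarray:
    return np.asarray([lab for lab, _ in predict(model, X)])


@dataclass
class GridSearchResult:
    grid_nh: tuple[int, ...]
    grid_ne: tuple[int, ...]
    accuracy: np.ndarray  # shape (len(grid_nh), len(grid_ne)), hold-out accuracy in %
    best_nh: int
    best_ne: int
    holdout_fraction: float


def grid_search(
    features,
    labels=None,
    grid_nh: Sequence[int] = DEFAULT_GRID_NH,
    grid_ne: Sequence[int] = DEFAULT_GRID_NE,
    seed: int = 0,
    holdout: float = 0.3,
    standardize: bool = True,
) -> GridSearchResult:
    """Hold-out tuning of (N_h, N_e) on a single stratified 70/30 split.

    The same split is reused for every grid cell; ties on the accuracy
    surface resolve to the smallest N_h, then the smallest N_e.
    """
    X, y = _coerce_features(features, labels)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout, stratify=y, random_state=seed
    )
    if set(y_tr) != set(y) or set(y_te) != set(y):
        raise ValueError("every class must appear in both the training and hold-out part")
    acc = np.zeros((len(grid_nh), len(grid_ne)))
    for i, nh in enumerate(grid_nh):
        for j, ne in enumerate(grid_ne):
            cfg = TrainingConfig(n_hidden=nh, n_epochs=ne, seed=seed, standardize=standardize)
            model = train_mlpnn(X_tr, cfg, labels=y_tr)
            pred = predict_labels(model, X_te)
            acc[i, j] = 100.0 * np.mean(pred == y_te)
    best_flat = np.argwhere(acc == acc.max())
    bi, bj = min(map(tuple, best_flat))  # smallest N_h, then smallest N_e
    return GridSearchResult(
        grid_nh=tuple(grid_nh),
        grid_ne=tuple(grid_ne),
        accuracy=acc,
        best_nh=int(grid_nh[bi]),
        best_ne=int(grid_ne[bj]),
        holdout_fraction=holdout,
    )
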