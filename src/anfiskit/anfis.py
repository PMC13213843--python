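"""Five-layer Sugeno ANFIS binary classifier.

The network implements the classic adaptive neuro-fuzzy inference system:

1. *Fuzzification* — each of the F normalised inputs is evaluated against a
   shared bank of three Gaussian membership functions (Low / Medium / High),
   ``mu(x) = exp(-(x - c)^2 / (2 sigma^2))``, with learnable centers and
   widths.
2. *Rule firing* — each of the R rules selects one membership function per
   feature; its firing strength is the product T-norm of the selected
   memberships, computed in log space with a small floor to avoid underflow
   across an 11-way product.
3. *Normalisation* — firing strengths are scaled to sum to one.
4. *Consequents* — first-order Sugeno: each rule contributes a linear
   function of the inputs, weighted by its normalised firing strength.
5. *Output* — a sigmoid maps the aggregated consequent to a probability.

All parameters (centers, widths, consequent coefficients and intercepts)
are trained jointly by minimising mean binary cross-entropy with Adam,
using hand-derived analytic gradients. Width positivity is maintained by
projection onto ``sigma >= sigma_min`` after each step.

The module exposes both the layer-level primitives (``gaussian_membership``,
``rule_firing``, ``normalize_firing``, ``forward``, ``train``) and a
statsmodels-style model/results pair (:class:`ANFISClassifier`,
:class:`ANFISResults`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    InvalidParameterError,
    ModelStateError,
    StratificationError,
    TrainingDivergedError,
)

MF_LABELS = ("Low", "Medium", "High")


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembershipFunction:
    """One Gaussian membership function with center ``c`` and width ``sigma``."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.center) and np.isfinite(self.width)):
            raise InvalidParameterError("membership parameters must be finite")
        if self.width <= 0:
            raise InvalidParameterError(f"width must be > 0, got {self.width}")


@dataclass(frozen=True)
class FuzzyRule:
    """One Sugeno rule: an MF index per feature plus a linear consequent."""

    antecedent: tuple[int, ...]
    coefficients: tuple[float, ...]
    intercept: float


@dataclass
class ANFISModel:
    """Parameter container for the five-layer network.

    ``centers`` and ``widths`` have shape (n_features, n_mfs) and are shared
    across rules (grid-partition style); ``antecedents`` is an integer array
    (n_rules, n_features) of MF indices; ``coefficients`` (n_rules,
    n_features) and ``intercepts`` (n_rules,) hold the first-order Sugeno
    consequents. ``epsilon`` floors per-feature memberships before the
    product so firing strengths never underflow to zero.
    """

    centers: np.ndarray
    widths: np.ndarray
    antecedents: np.ndarray
    coefficients: np.ndarray
    intercepts: np.ndarray
    feature_names: tuple[str, ...]
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        self.antecedents = np.asarray(self.antecedents, dtype=int)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        n_features, n_mfs = self.centers.shape
        if self.widths.shape != (n_features, n_mfs):
            raise InvalidParameterError("widths shape must match centers")
        if np.any(self.widths <= 0):
            raise InvalidParameterError("all widths must be > 0")
        if self.antecedents.shape[1] != n_features:
            raise InvalidParameterError("antecedent length must equal n_features")
        if self.antecedents.min() < 0 or self.antecedents.max() >= n_mfs:
            raise InvalidParameterError("antecedent MF indices out of range")
        if self.coefficients.shape != self.antecedents.shape:
            raise InvalidParameterError("one coefficient vector per rule required")
        for array in (self.centers, self.coefficients, self.intercepts):
            if not np.all(np.isfinite(array)):
                raise InvalidParameterError("model parameters must be finite")

    @property
    def n_features(self) -> int:
        return self.centers.shape[0]

    @property
    def n_mfs(self) -> int:
        return self.centers.shape[1]

    @property
    def n_rules(self) -> int:
        return self.antecedents.shape[0]

    @property
    def rules(self) -> list[FuzzyRule]:
        return [
            FuzzyRule(
                antecedent=tuple(int(a) for a in self.antecedents[k]),
                coefficients=tuple(float(c) for c in self.coefficients[k]),
                intercept=float(self.intercepts[k]),
            )
            for k in range(self.n_rules)
        ]

    def membership_bank(self, feature: int | str) -> tuple[MembershipFunction, ...]:
        """The ordered (Low, Medium, High) MF triple for one feature."""
        if isinstance(feature, str):
            feature = self.feature_names.index(feature)
        return tuple(
            MembershipFunction(float(c), float(s))
            for c, s in zip(self.centers[feature], self.widths[feature])
        )

    def copy(self) -> "ANFISModel":
        return ANFISModel(
            centers=self.centers.copy(),
            widths=self.widths.copy(),
            antecedents=self.antecedents.copy(),
            coefficients=self.coefficients.copy(),
            intercepts=self.intercepts.copy(),
            feature_names=tuple(self.feature_names),
            epsilon=self.epsilon,
        )

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "mf_labels": list(MF_LABELS[: self.n_mfs]),
            "centers": self.centers.tolist(),
            "widths": self.widths.tolist(),
            "antecedents": self.antecedents.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercepts": self.intercepts.tolist(),
            "epsilon": self.epsilon,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "ANFISModel":
        return cls(
            centers=np.array(raw["centers"], dtype=float),
            widths=np.array(raw["widths"], dtype=float),
            antecedents=np.array(raw["antecedents"], dtype=int),
            coefficients=np.array(raw["coefficients"], dtype=float),
            intercepts=np.array(raw["intercepts"], dtype=float),
            feature_names=tuple(raw["feature_names"]),
            epsilon=float(raw.get("epsilon", 1e-12)),
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation hyper-parameters for joint gradient training."""

    learning_rate: float = 0.01
    max_epochs: int = 100
    batch_size: int = 32
    early_stopping_patience: int = 10
    validation_fraction: float = 0.20
    seed: int = 0
    sigma_min: float = 0.01
    rule_init: str = "kmeans"  # or "random"

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.max_epochs, self.batch_size,
               self.early_stopping_patience) <= 0:
            raise InvalidParameterError("training hyper-parameters must be positive")
        if not 0.0 < self.validation_fraction < 1.0:
            raise InvalidParameterError("validation_fraction must be in (0, 1)")
        if self.rule_init not in ("kmeans", "random"):
            raise InvalidParameterError(f"unknown rule_init {self.rule_init!r}")


@dataclass
class TrainingHistory:
    """Per-epoch loss/accuracy traces and the best (restored) epoch index."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(self.n_epochs),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "train_acc": self.train_acc,
                "val_acc": self.val_acc,
            }
        )


# ---------------------------------------------------------------------------
# forward primitives
# ---------------------------------------------------------------------------

def gaussian_membership(x, mf: MembershipFunction):
    """Gaussian membership ``exp(-(x - c)^2 / (2 sigma^2))`` in (0, 1]."""
    if mf.width <= 0:
        raise InvalidParameterError("width must be > 0")
    x = np.asarray(x, dtype=float)
    out = np.exp(-((x - mf.center) ** 2) / (2.0 * mf.width**2))
    return float(out) if out.ndim == 0 else out


def _memberships(model: ANFISModel, X: np.ndarray) -> np.ndarray:
    """All membership values, shape (n, n_features, n_mfs)."""
    diff = X[:, :, None] - model.centers[None, :, :]
    return np.exp(-(diff**2) / (2.0 * model.widths[None, :, :] ** 2))


def _firing(model: ANFISModel, X: np.ndarray):
    """Firing strengths via a log-space product with the epsilon floor.

    Returns (w, mu_rule, floored) where ``mu_rule`` has shape (n, R, F) and
    ``floored`` marks memberships clamped at the floor (their gradient is
    treated as zero).
    """
    M = _memberships(model, X)
    F = model.n_features
    mu_rule = M[:, np.arange(F), model.antecedents]  # (n, R, F)
    floored = mu_rule < model.epsilon
    mu_safe = np.maximum(mu_rule, model.epsilon)
    w = np.exp(np.sum(np.log(mu_safe), axis=2))
    return w, mu_rule, floored


def rule_firing(x, model: ANFISModel) -> np.ndarray:
    """Firing strength of every rule for a single feature vector."""
    X = np.asarray(x, dtype=float).reshape(1, -1)
    w, _, _ = _firing(model, X)
    return w[0]


def normalize_firing(w) -> np.ndarray:
    """Scale firing strengths to sum to one."""
    w = np.asarray(w, dtype=float)
    total = w.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise InvalidParameterError("firing strengths sum to zero")
    return w / total


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))  # numerically stable sigmoid


def _forward_batch(model: ANFISModel, X: np.ndarray):
    """Forward pass returning all intermediates needed for backprop."""
    w, mu_rule, floored = _firing(model, X)
    total = w.sum(axis=1, keepdims=True)
    w_norm = w / total
    g = X @ model.coefficients.T + model.intercepts  # (n, R)
    z = np.sum(w_norm * g, axis=1)
    y = _sigmoid(z)
    return y, z, g, w, w_norm, total[:, 0], mu_rule, floored


def forward(x, model: ANFISModel):
    """Predicted probability for one feature vector or a batch."""
    X = np.asarray(x, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    y = _forward_batch(model, X)[0]
    return float(y[0]) if single else y


def predict_proba(model: ANFISModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return _forward_batch(model, np.atleast_2d(X))[0]


def _bce(y: np.ndarray, t: np.ndarray) -> float:
    p = np.clip(y, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))


def loss_and_gradients(model: ANFISModel, X: np.ndarray, t: np.ndarray):
    """Mean binary cross-entropy and its analytic gradients.

    Backpropagates through sigmoid, consequent mixing, firing-strength
    normalisation, the log-space product, and the Gaussian memberships.
    Memberships at the underflow floor receive zero gradient (clamp
    semantics).
    """
    n, F = X.shape
    y, z, g, w, w_norm, total, mu_rule, floored = _forward_batch(model, X)
    loss = _bce(y, t)

    dz = (y - t) / n  # d(mean BCE)/dz through the sigmoid
    # consequents
    weighted = w_norm * dz[:, None]  # (n, R)
    d_coef = weighted.T @ X
    d_inter = weighted.sum(axis=0)
    # normalised firing -> raw firing
    dw = dz[:, None] * (g - z[:, None]) / total[:, None]  # (n, R)
    d_mu = (dw * w)[:, :, None] / np.maximum(mu_rule, model.epsilon)  # (n, R, F)
    d_mu[floored] = 0.0
    # membership -> Gaussian parameters, accumulated over rules sharing MFs
    c_rule = model.centers[np.arange(F), model.antecedents]  # (R, F)
    s_rule = model.widths[np.arange(F), model.antecedents]
    diff = X[:, None, :] - c_rule[None, :, :]  # (n, R, F)
    common = d_mu * mu_rule
    dc_rf = np.sum(common * diff / s_rule**2, axis=0)  # (R, F)
    ds_rf = np.sum(common * diff**2 / s_rule**3, axis=0)
    d_centers = np.zeros_like(model.centers)
    d_widths = np.zeros_like(model.widths)
    f_idx = np.tile(np.arange(F), model.n_rules)
    k_idx = model.antecedents.ravel()
    np.add.at(d_centers, (f_idx, k_idx), dc_rf.ravel())
    np.add.at(d_widths, (f_idx, k_idx), ds_rf.ravel())
    grads = {
        "centers": d_centers,
        "widths": d_widths,
        "coefficients": d_coef,
        "intercepts": d_inter,
    }
    return loss, grads


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def _kmeans_antecedents(
    X: np.ndarray, n_rules: int, centers: np.ndarray, seed: int
) -> np.ndarray:
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_rules, n_init=10, random_state=seed)
    km.fit(X)
    # map each centroid coordinate to the nearest MF center of that feature
    dist = np.abs(km.cluster_centers_[:, :, None] - centers[None, :, :])
    antecedents = np.argmin(dist, axis=2)
    return _dedupe_antecedents(antecedents, X, centers)


def _dedupe_antecedents(
    antecedents: np.ndarray, X: np.ndarray, centers: np.ndarray
) -> np.ndarray:
    """Perturb duplicate antecedents to the next-nearest MF on the feature
    with the highest training variance, cycling to further features if
    needed."""
    n_mfs = centers.shape[1]
    order = np.argsort(-X.var(axis=0))  # features by descending variance
    seen: set[tuple] = set()
    for k in range(antecedents.shape[0]):
        key = tuple(antecedents[k])
        pos = 0
        while key in seen:
            f = order[pos % len(order)]
            antecedents[k, f] = (antecedents[k, f] + 1) % n_mfs
            key = tuple(antecedents[k])
            pos += 1
        seen.add(key)
    return antecedents


def initialize_model(
    X: np.ndarray,
    feature_names: tuple[str, ...],
    n_rules: int = 8,
    n_mfs: int = 3,
    seed: int = 0,
    rule_init: str = "kmeans",
    epsilon: float = 1e-12,
) -> ANFISModel:
    """Build the untrained network.

    MF centers start evenly spaced across [0, 1] (0, 0.5, 1 for three MFs)
    with width 0.25 so adjacent functions overlap substantially. Rule
    antecedents come from seeded k-means on the training features (each
    centroid snapped to the nearest MF center per feature, duplicates
    perturbed) or from a seeded uniform draw. Consequent coefficients start
    at zero with small random intercepts so rules are not identical.
    """
    n_features = X.shape[1]
    rng = np.random.default_rng(seed)
    centers = np.tile(np.linspace(0.0, 1.0, n_mfs), (n_features, 1))
    widths = np.full((n_features, n_mfs), 0.25)
    if rule_init == "kmeans":
        antecedents = _kmeans_antecedents(X, n_rules, centers, seed)
    else:
        antecedents = _dedupe_antecedents(
            rng.integers(0, n_mfs, size=(n_rules, n_features)), X, centers
        )
    coefficients = np.zeros((n_rules, n_features))
    intercepts = rng.normal(0.0, 0.1, size=n_rules)
    return ANFISModel(
        centers=centers,
        widths=widths,
        antecedents=antecedents,
        coefficients=coefficients,
        intercepts=intercepts,
        feature_names=tuple(feature_names),
        epsilon=epsilon,
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _stratified_indices(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Seeded stratified holdout; returns (main_idx, holdout_idx)."""
    holdout: list[np.ndarray] = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        k = int(round(fraction * len(members)))
        if k < 1 or k >= len(members):
            raise StratificationError(
                f"class {cls} too small for holdout fraction {fraction}"
            )
        holdout.append(rng.permutation(members)[:k])
    holdout_idx = np.sort(np.concatenate(holdout))
    mask = np.ones(len(y), dtype=bool)
    mask[holdout_idx] = False
    return np.flatnonzero(mask), holdout_idx


class _Adam:
    def __init__(self, shapes: dict, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for key, grad in grads.items():
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * grad
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * grad**2
            m_hat = self.m[key] / (1 - self.b1**self.t)
            v_hat = self.v[key] / (1 - self.b2**self.t)
            params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(
    X,
    y,
    config: TrainingConfig | None = None,
    model: ANFISModel | None = None,
    feature_names: tuple[str, ...] | None = None,
) -> tuple[ANFISModel, TrainingHistory]:
    """Fit the network by Adam on mean binary cross-entropy.

    A stratified ``validation_fraction`` of the data is held out to monitor
    validation loss; training stops once it fails to improve for
    ``early_stopping_patience`` epochs, and the best-epoch weights are
    restored. Deterministic for fixed data, config and seed.
    """
    config = config or TrainingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise StratificationError("training labels must contain both classes")
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(X.shape[1]))
    rng = np.random.default_rng(config.seed)
    train_idx, val_idx = _stratified_indices(y, config.validation_fraction, rng)
    X_tr, y_tr = X[train_idx], y[train_idx]
    X_val, y_val = X[val_idx], y[val_idx]

    if model is None:
        model = initialize_model(
            X_tr,
            feature_names,
            seed=config.seed,
            rule_init=config.rule_init,
        )
    else:
        model = model.copy()
    params = {
        "centers": model.centers,
        "widths": model.widths,
        "coefficients": model.coefficients,
        "intercepts": model.intercepts,
    }
    adam = _Adam({k: v.shape for k, v in params.items()}, config.learning_rate)

    history = TrainingHistory()
    best_val = np.inf
    best_params = None
    stale = 0
    n = len(X_tr)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            loss, grads = loss_and_gradients(model, X_tr[batch], y_tr[batch])
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            adam.step(params, grads)
            np.maximum(model.widths, config.sigma_min, out=model.widths)

        y_hat_tr = predict_proba(model, X_tr)
        y_hat_val = predict_proba(model, X_val)
        tr_loss, val_loss = _bce(y_hat_tr, y_tr), _bce(y_hat_val, y_val)
        if not (np.isfinite(tr_loss) and np.isfinite(val_loss)):
            raise TrainingDivergedError(epoch)
        history.train_loss.append(tr_loss)
        history.val_loss.append(val_loss)
        history.train_acc.append(float(np.mean((y_hat_tr > 0.5) == y_tr)))
        history.val_acc.append(float(np.mean((y_hat_val > 0.5) == y_val)))
        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stopping_patience:
                break

    if best_params is not None:
        for key, value in best_params.items():
            params[key][...] = value
    return model, history


# ---------------------------------------------------------------------------
# statsmodels-style model / results pair
# ---------------------------------------------------------------------------

class ANFISClassifier:
    """Sugeno ANFIS binary classifier over a feature matrix.

    Parameters
    ----------
    endog : array-like of 0/1
        Diagnosis labels.
    exog : array-like or DataFrame, shape (n, n_features)
        Normalised feature matrix in [0, 1].
    feature_names : sequence of str, optional
        Taken from the DataFrame columns when not given.
    n_rules, n_mfs : int
        Architecture size (defaults: 8 rules, 3 MFs per feature).
    """

    def __init__(self, endog, exog, feature_names=None, n_rules=8, n_mfs=3):
        if isinstance(exog, pd.DataFrame):
            if feature_names is None:
                feature_names = tuple(exog.columns)
            exog = exog.to_numpy(dtype=float)
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or len(self.endog) != len(self.exog):
            raise InvalidParameterError("endog and exog shapes are inconsistent")
        self.feature_names = tuple(
            feature_names
            if feature_names is not None
            else (f"x{i}" for i in range(self.exog.shape[1]))
        )
        self.n_rules = n_rules
        self.n_mfs = n_mfs

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, label_column: str = "diagnosis", **kwargs
    ) -> "ANFISClassifier":
        """Build from a table whose non-label columns are the features."""
        features = data.drop(columns=[label_column])
        return cls(data[label_column], features, **kwargs)

    def fit(self, config: TrainingConfig | None = None, **overrides) -> "ANFISResults":
        """Train and return an :class:`ANFISResults`.

        Keyword overrides (e.g. ``max_epochs=5``, ``seed=3``) replace fields
        of the supplied or default :class:`TrainingConfig`.
        """
        config = replace(config or TrainingConfig(), **overrides)
        model, history = train(
            self.exog, self.endog, config, feature_names=self.feature_names
        )
        return ANFISResults(self, model, history, config)


class ANFISResults:
    """Fitted ANFIS parameters plus training diagnostics."""

    def __init__(
        self,
        classifier: ANFISClassifier | None,
        model: ANFISModel,
        history: TrainingHistory | None,
        config: TrainingConfig | None = None,
        scaler=None,
    ):
        self.classifier = classifier
        self.model = model
        self.history = history or TrainingHistory()
        self.config = config
        self.scaler = scaler  # preprocessing.ScalerParams for raw-score input

    def predict_proba(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.model.feature_names)].to_numpy(dtype=float)
        return predict_proba(self.model, X)

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        """Hard labels; positive iff probability strictly exceeds threshold."""
        return (self.predict_proba(X) > threshold).astype(int)

    def evaluate(self, X, y):
        """MetricSet (incl. AUC) of the fitted model on a labelled set."""
        from . import evaluation

        probs = self.predict_proba(X)
        counts = evaluation.confusion(y, probs)
        metrics = evaluation.metrics_from_confusion(counts)
        metrics.auc = evaluation.roc_auc(y, probs)
        return metrics

    def summary(self) -> str:
        """Plain-text fit summary in the spirit of statsmodels results."""
        m, h = self.model, self.history
        lines = [
            "ANFIS classifier results",
            "=" * 60,
            f"features: {m.n_features}   membership functions/feature: {m.n_mfs}",
            f"rules: {m.n_rules}   consequent order: linear (first-order Sugeno)",
        ]
        if self.classifier is not None:
            n = len(self.classifier.endog)
            pos = int(self.classifier.endog.sum())
            lines.append(f"n obs: {n}   positives: {pos} ({pos / n:.1%})")
        if h.n_epochs:
            lines += [
                f"epochs run: {h.n_epochs}   best epoch: {h.best_epoch}",
                f"best validation loss: {h.val_loss[h.best_epoch]:.4f}"
                f"   validation accuracy: {h.val_acc[h.best_epoch]:.4f}",
            ]
        lines.append("-" * 60)
        lines.append("rule  antecedent (MF index per feature)      intercept")
        for k, rule in enumerate(m.rules):
            ant = "".join(str(a) for a in rule.antecedent)
            lines.append(f"{k:>4}  {ant:<40} {rule.intercept:+.4f}")
        return "\n".join(lines)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        payload = {"model": self.model.to_dict()}
        if self.scaler is not None:
            payload["scaler"] = self.scaler.to_dict()
        if self.history.n_epochs:
            payload["history"] = {
                "train_loss": self.history.train_loss,
                "val_loss": self.history.val_loss,
                "train_acc": self.history.train_acc,
                "val_acc": self.history.val_acc,
                "best_epoch": self.history.best_epoch,
            }
        return payload

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "ANFISResults":
        from .preprocessing import ScalerParams

        raw = json.loads(Path(path).read_text())
        history = TrainingHistory()
        if "history" in raw:
            h = raw["history"]
            history = TrainingHistory(
                train_loss=list(h["train_loss"]),
                val_loss=list(h["val_loss"]),
                train_acc=list(h["train_acc"]),
                val_acc=list(h["val_acc"]),
                best_epoch=int(h["best_epoch"]),
            )
        scaler = ScalerParams.from_dict(raw["scaler"]) if "scaler" in raw else None
        return cls(None, ANFISModel.from_dict(raw["model"]), history, scaler=scaler)


def require_trained(results: ANFISResults | ANFISModel) -> ANFISModel:
    """Return the underlying model, insisting that one exists."""
    model = results.model if isinstance(results, ANFISResults) else results
    if model is None:
        raise ModelStateError("a trained model is required")
    return model
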