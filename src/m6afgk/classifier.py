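"""Logistic regression trained by batch gradient descent.

The hypothesis is h_theta(x) = g(theta0 + sum_j theta_j x_j) with g the
logistic sigmoid; the cost is the mean cross-entropy

    J(theta) = (1/m) sum_i [ -y_i log h_i - (1-y_i) log (1-h_i) ]
             (+ lambda/(2m) * sum_{j>=1} theta_j^2 with ridge penalty)

minimized by full-batch gradient descent from theta = 0.  The update uses
the *mean* gradient so the step size alpha is invariant to corpus size.
The step size adapts monotonically in cost: any step that would increase
the cost halves alpha and is retried, and each accepted epoch grows alpha
by a small factor, so the realized cost sequence is non-increasing while
convergence does not stall at a conservatively small initial step.

The trainer is deliberately the from-equations implementation; established
solvers (e.g. LIBLINEAR-style) serve only as cross-checks in the test
suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateTrainingError,
    DivergenceError,
    FeatureMismatchError,
    LabelError,
)

_MIN_ALPHA = 1e-12
_ALPHA_GROWTH = 1.1  # per accepted epoch; halved on any cost increase


@dataclass(frozen=True)
class TrainConfig:
    alpha: float = 0.1          # initial step size; auto-halved on cost increase
    max_epochs: int = 5000
    tolerance: float = 1e-8     # stop when the cost decrease falls below this
    l2_lambda: float = 1.0      # ridge strength; intercept never penalized
    threshold: float = 0.5      # decision cut on the predicted probability
    seed: int = 0               # reserved for optional stochastic variants

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be positive")
        if self.tolerance < 0 or self.l2_lambda < 0:
            raise ConfigurationError("tolerance and l2_lambda must be >= 0")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError("threshold must be in (0, 1)")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")


@dataclass
class LogisticModel:
    """Fitted weights: theta[0] is the intercept, theta[1:] per feature."""

    theta: np.ndarray
    feature_fingerprint: str = ""
    config: TrainConfig = field(default_factory=TrainConfig)
    n_epochs: int = 0
    final_cost: float = float("nan")

    @property
    def n_features(self) -> int:
        return len(self.theta) - 1

    def save(self, path: str | Path) -> None:
        payload = {
            "feature_fingerprint": self.feature_fingerprint,
            "theta": [float(t) for t in self.theta],
            "config": asdict(self.config),
            "n_epochs": self.n_epochs,
            "final_cost": self.final_cost,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def load(path: str | Path) -> "LogisticModel":
        payload = json.loads(Path(path).read_text())
        return LogisticModel(
            theta=np.array(payload["theta"], dtype=float),
            feature_fingerprint=payload["feature_fingerprint"],
            config=TrainConfig(**payload["config"]),
            n_epochs=payload["n_epochs"],
            final_cost=payload["final_cost"],
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def hypothesis(model: LogisticModel, x: np.ndarray) -> float:
    """Predicted probability g(theta0 + theta . x) for one feature vector."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.n_features:
        raise FeatureMismatchError(
            f"vector has {x.shape[-1]} features, model expects {model.n_features}"
        )
    return float(_sigmoid(np.atleast_1d(model.theta[0] + x @ model.theta[1:]))[0])


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise LabelError("labels must be binary 0/1")
    return y.astype(float)


def cost(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
         l2_lambda: float = 0.0) -> float:
    """Mean cross-entropy (natural log) plus optional ridge term."""
    y = _check_labels(y)
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    z = theta[0] + X @ theta[1:]
    # -y log h - (1-y) log(1-h) == log(1 + e^z) - y z, stable for all z
    ce = float(np.mean(np.logaddexp(0.0, z) - y * z))
    if l2_lambda > 0:
        ce += l2_lambda / (2 * m) * float(np.dot(theta[1:], theta[1:]))
    return ce


def gradient(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
             l2_lambda: float = 0.0) -> np.ndarray:
    """Mean gradient of the cost; analytic form (h - y) averaged over rows."""
    y = _check_labels(y)
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    resid = _sigmoid(theta[0] + X @ theta[1:]) - y
    grad = np.empty_like(theta)
    grad[0] = resid.mean()
    grad[1:] = X.T @ resid / m
    if l2_lambda > 0:
        grad[1:] += l2_lambda / m * theta[1:]
    return grad


def fit(X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None,
        feature_fingerprint: str = "") -> LogisticModel:
    """Batch gradient descent from theta = 0; deterministic given config."""
    config = config or TrainConfig()
    y_arr = _check_labels(y)
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    if m < 2 or len(np.unique(y_arr)) < 2:
        raise DegenerateTrainingError("training needs >= 2 samples of both classes")

    lam = config.l2_lambda
    theta = np.zeros(X.shape[1] + 1)
    alpha = config.alpha
    # z = theta0 + X @ theta[1:] is maintained incrementally so each epoch
    # costs two mat-vec products (X @ grad and X.T @ resid)
    z = np.zeros(m)

    def penalized(zvec: np.ndarray, w: np.ndarray) -> float:
        c = float(np.mean(np.logaddexp(0.0, zvec) - y_arr * zvec))
        return c + lam / (2 * m) * float(w @ w) if lam > 0 else c

    current = penalized(z, theta[1:])
    epochs_done = 0
    for _ in range(config.max_epochs):
        resid = _sigmoid(z) - y_arr
        grad = np.empty_like(theta)
        grad[0] = resid.mean()
        grad[1:] = X.T @ resid / m
        if lam > 0:
            grad[1:] += lam / m * theta[1:]
        dz = grad[0] + X @ grad[1:]
        while True:
            z_new = z - alpha * dz
            candidate = theta - alpha * grad
            c = penalized(z_new, candidate[1:])
            if np.isfinite(c) and c <= current:
                break
            alpha /= 2
            if alpha < _MIN_ALPHA:
                if not np.isfinite(c):
                    raise DivergenceError(
                        "cost became non-finite; try a smaller alpha"
                    )
                candidate, z_new, c = theta, z, current  # stationary point
                break
        epochs_done += 1
        theta, z, previous, current = candidate, z_new, current, c
        if previous - current < config.tolerance:
            break
        alpha *= _ALPHA_GROWTH
    if not np.all(np.isfinite(theta)):
        raise DivergenceError("parameters diverged; try a smaller alpha")
    return LogisticModel(
        theta=theta,
        feature_fingerprint=feature_fingerprint,
        config=config,
        n_epochs=epochs_done,
        final_cost=cost(theta, X, y_arr, lam),
    )


def predict(model: LogisticModel, X: np.ndarray,
            threshold: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(labels, scores); score >= threshold classifies as positive."""
    threshold = model.config.threshold if threshold is None else threshold
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError("threshold must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise FeatureMismatchError(
            f"matrix has {X.shape[-1]} features, model expects {model.n_features}"
        )
    scores = _sigmoid(model.theta[0] + X @ model.theta[1:])
    return (scores >= threshold).astype(int), scores
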