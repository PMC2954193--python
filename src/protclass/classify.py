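"""SVM and feed-forward ANN classifiers behind one contract:
continuous decision score in, thresholded binary label out.

The SVM is a C-SVC with RBF kernel exp(-gamma*||u-v||^2), delegated to
scikit-learn; decision-function values are used raw (no probability
calibration), so scores near the margin span roughly [-1, 1]. A
configured C of 0 is mapped to the backend default C=1.0, since C=0 is
degenerate for C-SVC.

The ANN is a fully-connected single-hidden-layer network trained by
online (per-pattern) vanilla backpropagation against targets 1/0 for
positives/negatives. The sum-of-squared-errors (SSE) over the training
set is monitored after every cycle and the weight snapshot with minimal
SSE is the returned model, so over-training past the SSE minimum cannot
hurt the final classifier. Activations per layer are 'linear' or
'logistic'; weight initialization is seeded and uniform in [-0.5, 0.5].

Default decision thresholds: 0.0 for SVM scores, 0.5 for ANN outputs.
The label rule is ``score >= threshold`` everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.svm import SVC


class ClassifierError(ValueError):
    """Raised for invalid training input or model misuse."""


@dataclass(frozen=True)
class SVMConfig:
    """RBF-kernel C-SVC hyperparameters.

    gamma may be a positive float, 'scale' (1/(n_features * Var(X)), the
    default) or 'auto' (1/n_features). Compositional feature vectors
    live on the simplex with tiny pairwise distances, so a variance-
    scaled kernel width is needed for decision scores to spread over a
    usable range; a dimension-only gamma leaves the kernel nearly
    constant and the scores compressed into a band far narrower than the
    0.1 threshold-scan step.
    """

    C: float = 1.0
    gamma: "float | str" = "scale"
    kernel: str = "RBF"
    class_weight: "str | None" = None  # "balanced" opt-in; off by default

    def __post_init__(self) -> None:
        if self.kernel.upper() != "RBF":
            raise ClassifierError("only the RBF kernel is supported")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ClassifierError("gamma must be positive")
        if self.C < 0:
            raise ClassifierError("C must be non-negative")

    @property
    def effective_C(self) -> float:
        # C=0 is degenerate for C-SVC; treat it as "backend default".
        return 1.0 if self.C == 0 else float(self.C)


@dataclass(frozen=True)
class ANNConfig:
    """Feed-forward network topology and training schedule."""

    hidden_units: int = 2
    activations: tuple[str, str, str] = ("linear", "logistic", "logistic")
    learning_rate: float = 0.1
    max_cycles: int = 1000
    seed: int = 42

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ClassifierError("hidden_units must be >= 1")
        if self.learning_rate <= 0:
            raise ClassifierError("learning_rate must be positive")
        if self.max_cycles < 1:
            raise ClassifierError("max_cycles must be >= 1")
        for act in self.activations:
            if act not in ("linear", "logistic"):
                raise ClassifierError(f"unknown activation {act!r}")


@dataclass
class TrainedModel:
    """A fitted classifier plus the metadata needed to reuse it safely."""

    family: str  # "SVM" | "ANN"
    config: "SVMConfig | ANNConfig"
    encoding_name: str
    state: object
    training_summary: dict
    n_features: int

    @property
    def default_threshold(self) -> float:
        return 0.0 if self.family == "SVM" else 0.5


@dataclass(frozen=True)
class Prediction:
    """One sequence's score and thresholded decision."""

    sequence_id: str
    score: float
    threshold: float

    @property
    def label(self) -> int:
        return int(self.score >= self.threshold)


def _check_training_input(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2:
        raise ClassifierError("feature matrix must be 2-dimensional")
    if X.shape[0] != y.shape[0]:
        raise ClassifierError("features and labels have different lengths")
    if not np.all(np.isfinite(X)):
        raise ClassifierError("non-finite feature value in training input")
    if set(np.unique(y)) != {0, 1}:
        raise ClassifierError("training requires both classes present (labels 0 and 1)")
    return X, y


def train_svm(
    X: np.ndarray, y: np.ndarray, config: SVMConfig = SVMConfig(), encoding_name: str = ""
) -> TrainedModel:
    """Fit an RBF-kernel C-SVC; positive decision scores mean positive class."""
    X, y = _check_training_input(X, y)
    gamma = config.gamma
    if gamma == "auto":
        gamma = 1.0 / X.shape[1]
    elif gamma == "scale":
        gamma = 1.0 / (X.shape[1] * X.var())
    svc = SVC(C=config.effective_C, gamma=gamma, kernel="rbf", class_weight=config.class_weight)
    svc.fit(X, y)
    summary = {
        "C": config.effective_C,
        "gamma": float(gamma),
        "n_support": svc.n_support_.tolist(),
    }
    return TrainedModel(
        family="SVM",
        config=config,
        encoding_name=encoding_name,
        state=svc,
        training_summary=summary,
        n_features=X.shape[1],
    )


def _activate(name: str, z: np.ndarray) -> np.ndarray:
    if name == "linear":
        return z
    return 1.0 / (1.0 + np.exp(-z))


def _activate_deriv(name: str, a: np.ndarray) -> np.ndarray:
    # derivative expressed in terms of the activation output a
    if name == "linear":
        return np.ones_like(a)
    return a * (1.0 - a)


class _MLPState:
    """Weights of a 1-hidden-layer net; kept minimal and picklable."""

    def __init__(self, W1, b1, W2, b2, activations):
        self.W1, self.b1, self.W2, self.b2 = W1, b1, W2, b2
        self.activations = activations

    def forward(self, X: np.ndarray) -> np.ndarray:
        a_in = _activate(self.activations[0], X)
        h = _activate(self.activations[1], a_in @ self.W1 + self.b1)
        out = _activate(self.activations[2], h @ self.W2 + self.b2)
        return out.ravel()


def train_ann(
    X: np.ndarray, y: np.ndarray, config: ANNConfig = ANNConfig(), encoding_name: str = ""
) -> TrainedModel:
    """Train by online backpropagation, returning the minimum-SSE snapshot.

    Patterns are visited in dataset order each cycle (no shuffling), so
    training is exactly reproducible for a given seed, data and config.
    Raises :class:`ClassifierError` if the SSE becomes non-finite,
    naming the cycle.
    """
    X, y = _check_training_input(X, y)
    n, d = X.shape
    rng = np.random.default_rng(config.seed)
    act_in, act_hid, act_out = config.activations
    W1 = rng.uniform(-0.5, 0.5, size=(d, config.hidden_units))
    b1 = rng.uniform(-0.5, 0.5, size=config.hidden_units)
    W2 = rng.uniform(-0.5, 0.5, size=(config.hidden_units, 1))
    b2 = rng.uniform(-0.5, 0.5, size=1)
    lr = config.learning_rate
    target = y.astype(float)
    a_input = _activate(act_in, X)

    best = None
    best_sse = np.inf
    best_cycle = -1
    sse_trace: list[float] = []
    for cycle in range(1, config.max_cycles + 1):
        for i in range(n):
            x_i = a_input[i]
            h = _activate(act_hid, x_i @ W1 + b1)
            o = _activate(act_out, h @ W2 + b2)
            err = o - target[i]
            delta_o = err * _activate_deriv(act_out, o)  # shape (1,)
            delta_h = (W2 @ delta_o) * _activate_deriv(act_hid, h)
            W2 -= lr * np.outer(h, delta_o)
            b2 -= lr * delta_o
            W1 -= lr * np.outer(x_i, delta_h)
            b1 -= lr * delta_h
        out = _activate(act_out, _activate(act_hid, a_input @ W1 + b1) @ W2 + b2).ravel()
        sse = float(np.sum((out - target) ** 2))
        if not np.isfinite(sse):
            raise ClassifierError(f"training diverged (non-finite SSE) at cycle {cycle}")
        sse_trace.append(sse)
        if sse < best_sse:
            best_sse = sse
            best_cycle = cycle
            best = _MLPState(W1.copy(), b1.copy(), W2.copy(), b2.copy(), config.activations)

    summary = {
        "final_sse": sse_trace[-1],
        "best_sse": best_sse,
        "best_cycle": best_cycle,
        "sse_trace": sse_trace,
    }
    return TrainedModel(
        family="ANN",
        config=config,
        encoding_name=encoding_name,
        state=best,
        training_summary=summary,
        n_features=d,
    )


def decision_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Continuous decision values (SVM margin scores or ANN outputs)."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.empty(0)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ClassifierError(
            f"model expects {model.n_features} features, got shape {X.shape}"
        )
    if model.family == "SVM":
        return model.state.decision_function(X)
    return model.state.forward(X)


def predict(
    model: TrainedModel,
    X: np.ndarray,
    ids: "Sequence[str] | None" = None,
    threshold: "float | None" = None,
) -> list[Prediction]:
    """Score each row and apply the threshold rule ``score >= threshold``."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return []
    th = model.default_threshold if threshold is None else float(threshold)
    scores = decision_scores(model, X)
    if ids is None:
        ids = [f"seq{i + 1}" for i in range(len(scores))]
    if len(ids) != len(scores):
        raise ClassifierError("ids and feature rows have different lengths")
    return [Prediction(sequence_id=i, score=float(s), threshold=th) for i, s in zip(ids, scores)]


_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path) -> None:
    """Persist a model to a single self-describing file."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "family": model.family,
        "config": asdict(model.config),
        "encoding_name": model.encoding_name,
        "state": model.state,
        "training_summary": model.training_summary,
        "n_features": model.n_features,
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ClassifierError("unrecognized model file format")
    cfg_cls = SVMConfig if payload["family"] == "SVM" else ANNConfig
    cfg = payload["config"]
    if "activations" in cfg:
        cfg["activations"] = tuple(cfg["activations"])
    return TrainedModel(
        family=payload["family"],
        config=cfg_cls(**cfg),
        encoding_name=payload["encoding_name"],
        state=payload["state"],
        training_summary=payload["training_summary"],
        n_features=payload["n_features"],
    )
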