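"""RVFL and ELM classifiers with closed-form ridge output weights; SVM baseline.

A random vector functional link (RVFL) network maps inputs through a single
hidden layer with *random, untrained* weights and solves only the output
weights, in closed form, as a ridge regression onto +/-1 labels:

    H = g(X W + b),  D = [X | H | 1]  (the direct-link block X is the RVFL
    hallmark; dropping it gives an extreme learning machine, ELM),
    beta = argmin ||D beta - y||^2 + lambda ||beta||^2.

The continuous decision value ``D beta`` doubles as the score for ROC/AUC; the
label is its sign (0 maps to +1). The SVM baseline is a thin adapter over
scikit-learn's SVC exposing decision-function scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "RVFLConfig",
    "RVFLModel",
    "rvfl_train",
    "rvfl_predict",
    "elm_train",
    "elm_predict",
    "svm_baseline",
    "SVMBaseline",
]


@dataclass(frozen=True)
class RVFLConfig:
    """Hyperparameters of the RVFL/ELM family.

    ``direct_links=True`` is the RVFL; ``False`` is the ELM. Random hidden
    weights/biases are i.i.d. Uniform(-init_scale, init_scale) from ``seed``.
    """

    n_hidden: int = 100
    activation: str = "sigmoid"  # or "relu"
    init_scale: float = 1.0
    ridge_lambda: float = 0.1
    direct_links: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden < 0:
            raise ValueError("n_hidden must be >= 0")
        if self.n_hidden == 0 and not self.direct_links:
            raise ValueError("ELM (no direct links) needs n_hidden >= 1")
        if self.activation not in ("sigmoid", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if not self.init_scale > 0:
            raise ValueError("init_scale must be > 0")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")


@dataclass
class RVFLModel:
    hidden_weights: np.ndarray  # d x L
    hidden_biases: np.ndarray  # L
    output_weights: np.ndarray  # d*[direct] + L + 1
    config: RVFLConfig
    feature_dim: int


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    return np.maximum(z, 0.0)


def _design(X: np.ndarray, model_or_cfg, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    cfg = model_or_cfg
    blocks = []
    if cfg.direct_links:
        blocks.append(X)
    if cfg.n_hidden > 0:
        blocks.append(_activate(X @ W + b, cfg.activation))
    blocks.append(np.ones((X.shape[0], 1)))
    return np.hstack(blocks)


def rvfl_train(X: np.ndarray, y: Sequence[int], config: RVFLConfig | None = None) -> RVFLModel:
    """Train an RVFL (or, via config, ELM): random hidden layer + ridge solve.

    ``y`` must be +/-1 labels (positive class = +1). Deterministic given
    ``config.seed``. Output weights solve the penalised normal equations; with
    ``ridge_lambda == 0`` the minimum-norm least-squares solution is used.
    """
    config = config or RVFLConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    if X.shape[0] < 2 or np.unique(y).size < 2:
        raise ValueError("need >= 2 samples and both classes present")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be coded +1 / -1")
    d = X.shape[1]
    rng = np.random.default_rng(config.seed)
    W = rng.uniform(-config.init_scale, config.init_scale, (d, config.n_hidden))
    b = rng.uniform(-config.init_scale, config.init_scale, config.n_hidden)
    D = _design(X, config, W, b)
    lam = config.ridge_lambda
    if lam > 0:
        beta = np.linalg.solve(D.T @ D + lam * np.eye(D.shape[1]), D.T @ y)
    else:
        beta = np.linalg.lstsq(D, y, rcond=None)[0]
    return RVFLModel(hidden_weights=W, hidden_biases=b, output_weights=beta,
                     config=config, feature_dim=d)


def rvfl_predict(model: RVFLModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores ``D beta`` and sign labels (+1 on ties) for new rows."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.feature_dim:
        raise ValueError(
            f"expected {model.feature_dim} feature columns, got {X_new.shape[1] if X_new.ndim == 2 else 'non-2D'}"
        )
    D = _design(X_new, model.config, model.hidden_weights, model.hidden_biases)
    scores = D @ model.output_weights
    labels = np.where(scores >= 0.0, 1, -1)
    return scores, labels


def elm_train(X: np.ndarray, y: Sequence[int], config: RVFLConfig | None = None) -> RVFLModel:
    """ELM = RVFL without the direct-link block (design ``[H | 1]``)."""
    config = config or RVFLConfig(direct_links=False)
    if config.direct_links:
        config = RVFLConfig(**{**config.__dict__, "direct_links": False})
    return rvfl_train(X, y, config)


elm_predict = rvfl_predict


class SVMBaseline:
    """Thin RBF-SVM comparison baseline over scikit-learn's SVC.

    Fixed, logged hyperparameters (C=1, gamma=1/d) — a reference point, not a
    tuned competitor. ``predict`` returns (decision scores, +/-1 labels).
    """

    def __init__(self, C: float = 1.0, gamma: float | str = "auto", kernel: str = "rbf"):
        self.params = {"C": C, "gamma": gamma, "kernel": kernel}
        self._svc = SVC(C=C, gamma=gamma, kernel=kernel)

    def fit(self, X: np.ndarray, y: Sequence[int]) -> "SVMBaseline":
        self._svc.fit(np.asarray(X, float), np.asarray(y))
        return self

    def predict(self, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        scores = self._svc.decision_function(np.asarray(X_new, float))
        labels = np.where(scores >= 0.0, 1, -1)
        return scores, labels


def svm_baseline(X: np.ndarray, y: Sequence[int], **params) -> SVMBaseline:
    """Fit the SVM baseline on (+/-1-labelled) training data."""
    return SVMBaseline(**params).fit(X, y)
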