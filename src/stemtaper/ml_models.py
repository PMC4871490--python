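"""Pooled machine-learning taper regressors: an Rprop MLP and a random forest.

Both regressors consume the same fixed six-element input encoding
``[dbh/100, ht/10, h/10, d1, d2, d3]`` where d1..d3 one-hot code the forest
type in the order cerrado, semideciduous, rainforest.  One model is trained
per target (diameter in cm, or accumulated volume in m^3); targets are left
unscaled by default.

The network has two logistic hidden layers (25 and 10 units) and a linear
output, trained full-batch to minimise the sum of squared errors by resilient
backpropagation with weight backtracking (Rprop+): per-weight step sizes grow
by ``eta_plus`` while the gradient sign persists, shrink by ``eta_minus`` and
revert the last step on a sign flip.  Training stops when the largest
absolute error-gradient component falls below ``grad_stop``; each training
event runs ``n_restarts`` independent initialisations and keeps the restart
with the lowest training SSE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .stem_geometry import FOREST_TYPES

__all__ = [
    "NNConfig",
    "RFConfig",
    "build_input_vector",
    "build_input_matrix",
    "NNRegressor",
    "RFRegressorWrapper",
    "train_nn",
    "train_rf",
    "predict",
]

_FOREST_INDEX = {name: i for i, name in enumerate(FOREST_TYPES)}

#: Scaling divisors for the continuous predictors dbh, ht, h.
_SCALES = np.array([100.0, 10.0, 10.0])


def build_input_vector(dbh: float, ht: float, h: float, forest_type: str) -> np.ndarray:
    """Scaled predictor vector ``[dbh/100, ht/10, h/10, d1, d2, d3]``."""
    if forest_type not in _FOREST_INDEX:
        raise ValueError(
            f"unknown forest_type {forest_type!r}; expected one of {FOREST_TYPES}"
        )
    if not (dbh > 0 and ht > 0 and h > 0):
        raise ValueError("dbh, ht and h must be positive")
    vec = np.zeros(6)
    vec[:3] = np.array([dbh, ht, h]) / _SCALES
    vec[3 + _FOREST_INDEX[forest_type]] = 1.0
    return vec


def build_input_matrix(rows: pd.DataFrame) -> np.ndarray:
    """Vectorised :func:`build_input_vector` over a DataFrame of observations.

    Requires columns ``dbh``, ``ht``, ``h``, ``forest_type``.
    """
    forests = rows["forest_type"].to_numpy()
    unknown = set(forests) - set(FOREST_TYPES)
    if unknown:
        raise ValueError(f"unknown forest types {sorted(unknown)!r}")
    X = np.zeros((len(rows), 6))
    X[:, 0] = rows["dbh"].to_numpy(float) / 100.0
    X[:, 1] = rows["ht"].to_numpy(float) / 10.0
    X[:, 2] = rows["h"].to_numpy(float) / 10.0
    for name, j in _FOREST_INDEX.items():
        X[:, 3 + j] = forests == name
    return X


@dataclass(frozen=True)
class NNConfig:
    hidden_sizes: tuple[int, int] = (25, 10)
    n_restarts: int = 50
    grad_stop: float = 0.01
    max_epochs: int = 10_000
    step_init: float = 0.1
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    step_min: float = 1e-6
    step_max: float = 50.0
    scale_targets: bool = False

    def __post_init__(self):
        if any(s <= 0 for s in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if self.grad_stop <= 0:
            raise ValueError("grad_stop must be > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 300
    m_try: int = 2
    min_node_size: int = 5

    def __post_init__(self):
        if not (1 <= self.m_try <= 6):
            raise ValueError("m_try must be between 1 and the 6 predictors")


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class NNRegressor:
    """A 6 -> 25 -> 10 -> 1 perceptron trained by Rprop+ (see module docs)."""

    def __init__(self, weights: list[np.ndarray], biases: list[np.ndarray],
                 config: NNConfig, converged: bool, train_sse: float,
                 n_epochs: int, target_scale: float = 1.0):
        self.weights = weights
        self.biases = biases
        self.config = config
        self.converged = converged
        self.train_sse = train_sse
        self.n_epochs = n_epochs
        self.target_scale = target_scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.weights[0].shape[0]:
            raise ValueError(
                f"expected {self.weights[0].shape[0]} input columns, "
                f"got {X.shape[1]}"
            )
        a = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = _logistic(a @ W + b)
        out = a @ self.weights[-1] + self.biases[-1]
        return out[:, 0] * self.target_scale


def _init_params(sizes: Sequence[int], rng: np.random.Generator):
    weights = [rng.normal(size=(a, b)) for a, b in zip(sizes[:-1], sizes[1:])]
    biases = [rng.normal(size=b) for b in sizes[1:]]
    return weights, biases


def _forward_backward(weights, biases, X, y):
    """SSE loss and its gradients for the logistic-hidden / linear-output net."""
    acts = [X]
    a = X
    for W, b in zip(weights[:-1], biases[:-1]):
        a = _logistic(a @ W + b)
        acts.append(a)
    out = (a @ weights[-1] + biases[-1])[:, 0]
    err = out - y
    sse = float(err @ err)

    grads_w = [None] * len(weights)
    grads_b = [None] * len(biases)
    delta = 2.0 * err[:, None]  # d SSE / d out
    grads_w[-1] = acts[-1].T @ delta
    grads_b[-1] = delta.sum(axis=0)
    back = delta @ weights[-1].T
    for layer in range(len(weights) - 2, -1, -1):
        a = acts[layer + 1]
        back = back * a * (1.0 - a)  # logistic derivative
        grads_w[layer] = acts[layer].T @ back
        grads_b[layer] = back.sum(axis=0)
        if layer > 0:
            back = back @ weights[layer].T
    return sse, grads_w, grads_b, out


def _train_once(X, y, config: NNConfig, rng: np.random.Generator):
    sizes = [X.shape[1], *config.hidden_sizes, 1]
    weights, biases = _init_params(sizes, rng)
    params = weights + biases
    steps = [np.full(p.shape, config.step_init) for p in params]
    prev_grad = [np.zeros(p.shape) for p in params]
    prev_delta = [np.zeros(p.shape) for p in params]

    converged = False
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        sse, gw, gb, _ = _forward_backward(weights, biases, X, y)
        grads = gw + gb
        gmax = max(np.max(np.abs(g)) for g in grads)
        if gmax < config.grad_stop:
            converged = True
            break
        for p, g, st, pg, pd in zip(params, grads, steps, prev_grad, prev_delta):
            sign = g * pg
            grow = sign > 0
            flip = sign < 0
            st[grow] = np.minimum(st[grow] * config.eta_plus, config.step_max)
            st[flip] = np.maximum(st[flip] * config.eta_minus, config.step_min)
            delta = -np.sign(g) * st
            delta[flip] = -pd[flip]  # weight backtracking: undo the last step
            p += delta
            g[flip] = 0.0  # Rprop+: skip the adaptation next epoch
            pg[...] = g
            pd[...] = delta
    final_sse, _, _, _ = _forward_backward(weights, biases, X, y)
    return weights, biases, converged, final_sse, epoch


def train_nn(X: np.ndarray, y: np.ndarray, config: NNConfig | None = None,
             seed: int = 0) -> NNRegressor:
    """Train the perceptron; best of ``config.n_restarts`` seeded restarts.

    If no restart reaches the gradient criterion the lowest-SSE network is
    still returned, flagged ``converged=False``.
    """
    config = config or NNConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(X) == 0:
        raise ValueError("no training rows")
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")

    scale = 1.0
    if config.scale_targets:
        scale = max(float(np.max(np.abs(y))), 1e-12)
    y_fit = y / scale

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(config.n_restarts):
        result = _train_once(X, y_fit, config, rng)
        if best is None or result[3] < best[3]:
            best = result
    weights, biases, converged, sse, epochs = best
    return NNRegressor(weights, biases, config, converged,
                       sse * scale * scale, epochs, target_scale=scale)


class RFRegressorWrapper:
    """Random forest with the fixed taper-study hyperparameters."""

    def __init__(self, model: RandomForestRegressor, config: RFConfig):
        self.model = model
        self.config = config
        self.train_range = (
            float(np.min(model._train_target_min)),
            float(np.max(model._train_target_max)),
        ) if hasattr(model, "_train_target_min") else None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return self.model.predict(X)


def train_rf(X: np.ndarray, y: np.ndarray, config: RFConfig | None = None,
             seed: int = 0) -> RFRegressorWrapper:
    """300-tree regression forest, 2 candidate predictors per split,
    terminal nodes no smaller than 5 observations."""
    config = config or RFConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(X) == 0:
        raise ValueError("no training rows")
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    model = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=config.m_try,
        min_samples_leaf=config.min_node_size,
        criterion="squared_error",
        random_state=int(seed) % (2**32),
        n_jobs=1,
    )
    model.fit(X, y)
    model._train_target_min = float(np.min(y))
    model._train_target_max = float(np.max(y))
    return RFRegressorWrapper(model, config)


def predict(model, X, target_kind: str = "d") -> np.ndarray:
    """Batched prediction; diameter predictions are clipped at zero."""
    if target_kind not in ("d", "vac"):
        raise ValueError("target_kind must be 'd' or 'vac'")
    X = np.asarray(X, float)
    if X.size == 0:
        return np.empty(0)
    out = model.predict(np.atleast_2d(X))
    if not np.all(np.isfinite(out)):
        raise ValueError("model produced non-finite predictions")
    if target_kind == "d":
        out = np.clip(out, 0.0, None)
    return out
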