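"""SVR hyperparameter semantics and the fitness the optimizer minimizes.

The optimizer searches a 3-D box whose coordinates decode directly to the
SVR hyperparameters ``(C, g, eps)``.  ``g`` is the RBF *width*: the kernel is
``exp(-||x - x'||² / g²)``, so the solver's gamma coefficient must be set to
``1/g²`` (not the library default parameterization).

The fitness is the mean RMSE over forward-chaining contiguous time-series
folds of the training block: each fold trains on all earlier rows and
validates on the next block, so no future information leaks backwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import TimeSeriesSplit
from sklearn.svm import SVR

from .metrics import StandardizationParams

__all__ = [
    "SVRHyperparams",
    "FitnessConfig",
    "decode_position",
    "kernel_coefficient",
    "cv_fitness",
    "fit_predict_svr",
    "make_objective",
]

DEFAULT_HYPERPARAMS = (1.0, 0.1, 0.1)  # plain-SVR baseline (C, g, eps)


@dataclass(frozen=True)
class SVRHyperparams:
    """Penalty C, RBF width g, and insensitive-loss half-width eps."""

    C: float
    g: float
    eps: float

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.g <= 0:
            raise ValueError("g must be positive")
        if self.eps < 0:
            raise ValueError("eps must be non-negative")

    def to_csv_row(self) -> str:
        return f"C,g,epsilon\n{self.C!r},{self.g!r},{self.eps!r}\n"


@dataclass(frozen=True)
class FitnessConfig:
    """Cross-validation setup for the tuning fitness (RMSE, minimized)."""

    folds: int = 5
    max_train_size: int | None = None

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def decode_position(position) -> SVRHyperparams:
    """Map an optimizer position ``[C, g, eps]`` to hyperparameters."""
    pos = np.asarray(position, dtype=float)
    if pos.shape != (3,):
        raise ValueError("position must be a 3-vector (C, g, eps)")
    return SVRHyperparams(C=float(pos[0]), g=float(pos[1]), eps=float(pos[2]))


def kernel_coefficient(g: float) -> float:
    """Gamma multiplier ``1/g²`` so the fitted kernel is exp(-d²/g²)."""
    if g <= 0:
        raise ValueError("g must be positive")
    return 1.0 / g**2


def _svr(params: SVRHyperparams) -> SVR:
    return SVR(kernel="rbf", C=params.C, gamma=kernel_coefficient(params.g), epsilon=params.eps)


def cv_fitness(X, y, params: SVRHyperparams, config: FitnessConfig = FitnessConfig()) -> float:
    """Mean validation RMSE over forward-chaining folds; deterministic."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D and aligned with y")
    if config.folds > X.shape[0] - 1:
        raise ValueError("more folds than available rows")
    splitter = TimeSeriesSplit(n_splits=config.folds, max_train_size=config.max_train_size)
    rmses = []
    for train_idx, val_idx in splitter.split(X):
        if val_idx.size < 2:
            raise ValueError("validation fold has fewer than 2 rows")
        model = _svr(params).fit(X[train_idx], y[train_idx])
        resid = y[val_idx] - model.predict(X[val_idx])
        rmses.append(float(np.sqrt(np.mean(resid**2))))
    return float(np.mean(rmses))


def fit_predict_svr(
    X_train,
    y_train,
    X_test,
    params: SVRHyperparams,
    target_params: StandardizationParams | None = None,
) -> np.ndarray:
    """Fit an RBF SVR on the training block and predict the test inputs.

    Inputs are expected already standardized; when ``target_params`` is
    given, predictions are mapped back to original target units.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_train.shape[0] == 0:
        raise ValueError("empty training set")
    if X_test.ndim != 2 or X_test.shape[1] != X_train.shape[1]:
        raise ValueError("feature count mismatch between train and test")
    if not (np.isfinite(X_train).all() and np.isfinite(y_train).all() and np.isfinite(X_test).all()):
        raise ValueError("non-finite values in inputs")
    if X_test.shape[0] == 0:
        return np.empty(0)
    pred = _svr(params).fit(X_train, y_train).predict(X_test)
    if target_params is not None:
        pred = target_params.inverse(pred)
    return pred


def make_objective(X, y, config: FitnessConfig = FitnessConfig()):
    """Objective closure for the optimizer: position -> cv RMSE."""

    def objective(position: np.ndarray) -> float:
        return cv_fitness(X, y, decode_position(position), config)

    return objective
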