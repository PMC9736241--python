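"""Column standardization and forecast evaluation metrics.

The five metrics (MAE, RMSE, MSE, NRMSE, R²) follow the conventions used
throughout this package:

* NRMSE is RMSE divided by the mean of the observed series.
* R² is the explained-variance ratio ``sum((pred - mean)²) / sum((obs -
  mean)²)`` with the mean taken over the observed values.  This equals the
  familiar ``1 - SSres/SStot`` form only when residuals are orthogonal to the
  centered predictions (e.g. an OLS fit); :func:`evaluate` can report both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StandardizationParams",
    "MetricsReport",
    "standardize",
    "Standardizer",
    "evaluate",
]


@dataclass(frozen=True)
class StandardizationParams:
    """Mean and population standard deviation of a single column."""

    mean: float
    std: float

    def forward(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.std

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.std + self.mean


def standardize(column, name: str = "column") -> tuple[np.ndarray, StandardizationParams]:
    """Center and scale ``column`` to zero mean and unit variance.

    Uses the population standard deviation (``ddof=0``).  Raises
    ``ValueError`` naming the column when it is constant or too short.
    """
    x = np.asarray(column, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name}: expected a 1-D column")
    if x.size < 2:
        raise ValueError(f"{name}: need at least 2 values to standardize")
    mean = float(np.mean(x))
    std = float(np.std(x))
    if std == 0.0 or not np.isfinite(std):
        raise ValueError(f"{name}: constant or non-finite column cannot be standardized")
    params = StandardizationParams(mean=mean, std=std)
    return params.forward(x), params


class Standardizer:
    """Per-column standardization for 2-D feature matrices.

    Parameters are fit once (on the training block) and reused, so test data
    never leaks into the scaling.
    """

    def __init__(self) -> None:
        self.params_: list[StandardizationParams] | None = None

    def fit(self, X: np.ndarray, names: list[str] | None = None) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        names = names or [f"column {j}" for j in range(X.shape[1])]
        self.params_ = [standardize(X[:, j], name=names[j])[1] for j in range(X.shape[1])]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("Standardizer is not fitted")
        X = np.asarray(X, dtype=float)
        return np.column_stack([p.forward(X[:, j]) for j, p in enumerate(self.params_)])

    def fit_transform(self, X: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        return self.fit(X, names).transform(X)


@dataclass(frozen=True)
class MetricsReport:
    """Evaluation metrics for one prediction run.

    ``r2`` is the explained-variance ratio (may exceed 1);
    ``r2_conventional`` is ``1 - SSres/SStot`` for comparison.
    """

    mae: float
    rmse: float
    mse: float
    nrmse: float
    r2: float
    r2_conventional: float

    def as_dict(self) -> dict[str, float]:
        return {
            "MAE": self.mae,
            "RMSE": self.rmse,
            "MSE": self.mse,
            "NRMSE": self.nrmse,
            "R2": self.r2,
        }

    def to_csv_row(self) -> str:
        d = self.as_dict()
        header = ",".join(d)
        values = ",".join(repr(v) for v in d.values())
        return f"{header}\n{values}\n"


def evaluate(actual, predicted) -> MetricsReport:
    """Compute MAE/RMSE/MSE/NRMSE/R² of ``predicted`` against ``actual``.

    ``actual`` must have at least 2 entries and a non-zero mean (for NRMSE).
    A zero-variance ``actual`` makes R² undefined; it is reported as NaN with
    a warning rather than raising, so perfect-constant edge cases still
    produce the error metrics.
    """
    f = np.asarray(actual, dtype=float)
    fp = np.asarray(predicted, dtype=float)
    if f.shape != fp.shape or f.ndim != 1:
        raise ValueError("actual and predicted must be 1-D vectors of equal length")
    if f.size < 2:
        raise ValueError("need at least 2 observations")
    if not (np.isfinite(f).all() and np.isfinite(fp).all()):
        raise ValueError("non-finite values in inputs")

    err = f - fp
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    fbar = float(np.mean(f))
    if fbar == 0.0:
        raise ValueError("mean of actual is zero; NRMSE undefined")
    nrmse = rmse / fbar

    sstot = float(np.sum((f - fbar) ** 2))
    if sstot == 0.0:
        warnings.warn("zero-variance actual: R² undefined, reported as NaN")
        r2 = float("nan")
        r2_conv = float("nan")
    elif mse == 0.0:
        # perfect prediction: both forms are exactly 1
        r2 = 1.0
        r2_conv = 1.0
    else:
        r2 = float(np.sum((fp - fbar) ** 2)) / sstot
        r2_conv = 1.0 - float(np.sum(err**2)) / sstot
    return MetricsReport(mae=mae, rmse=rmse, mse=mse, nrmse=nrmse, r2=r2, r2_conventional=r2_conv)
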