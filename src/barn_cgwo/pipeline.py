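"""End-to-end forecasting pipeline.

Five stages: repair the raw table, rank features by GOSS gain and keep the
top k, standardize with training-block parameters and split 70/30
chronologically, tune SVR hyperparameters with the (C)GWO optimizer on the
training block, then fit, predict the held-out block and report metrics in
original humidity units.  Every stage that estimates anything (importances,
scaling, hyperparameters) sees the training block only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_barn
from .chaotic_gwo import OptimizeResult, SearchSpace, optimize
from .goss_importance import FeatureImportance, GossConfig, fit_goss_gbdt, select_features
from .metrics import MetricsReport, Standardizer, evaluate, standardize
from .svr_objective import (
    DEFAULT_HYPERPARAMS,
    FitnessConfig,
    SVRHyperparams,
    decode_position,
    fit_predict_svr,
    make_objective,
)

__all__ = [
    "ForecastDataset",
    "PipelineConfig",
    "repair",
    "build_forecast_dataset",
    "chronological_split",
    "run_pipeline",
]

logger = logging.getLogger("barn_cgwo")

#: columns that can never be negative (temperature may drop below zero)
_NON_NEGATIVE = [c for c in synthetic_barn.COLUMNS if c != "air_temp"]


@dataclass
class ForecastDataset:
    """Inputs at time t paired with the target ``horizon`` steps later."""

    X: pd.DataFrame
    y: pd.Series
    horizon: int
    feature_names: list[str]

    def __len__(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run depends on; the run is a pure function of this."""

    input_csv: str | None = None
    generator: synthetic_barn.GeneratorConfig | None = None
    k_features: int = 4
    horizon: int = 1  # steps of 10 min
    train_frac: float = 0.7
    include_target_lag: bool = False
    shuffle_split: bool = False
    pack_size: int = 20
    max_iter: int = 20
    variant: str = "cgwo"
    search_lo: float = 0.01
    search_hi: float = 10.0
    goss: GossConfig = field(default_factory=GossConfig)
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    seed: int = 0
    outdir: str | None = None
    baselines: tuple[str, ...] = ("default_svr",)

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


def repair(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Fill missing and physically impossible readings by interpolation.

    Humidity outside [0, 100] and negative readings on non-negative channels
    are treated as missing, then every gap is linearly interpolated between
    its nearest valid neighbors (nearest-value fill at the edges).  Returns
    the repaired table and the number of repaired cells; raises when any
    column has more than 20 % of its values to repair.
    """
    if not table.index.is_monotonic_increasing:
        raise ValueError("timestamps must be sorted")
    out = table.copy()
    if "air_humidity" in out:
        bad = (out["air_humidity"] < 0) | (out["air_humidity"] > 100)
        out.loc[bad, "air_humidity"] = np.nan
    for col in _NON_NEGATIVE:
        if col != "air_humidity" and col in out:
            out.loc[out[col] < 0, col] = np.nan
    n_missing = out.isna().sum()
    limit = 0.2 * len(out)
    over = n_missing[n_missing > limit]
    if not over.empty:
        raise ValueError(f"more than 20% missing/invalid in column(s): {list(over.index)}")
    count = int(n_missing.sum())
    if count:
        out = out.interpolate(method="linear", limit_direction="both")
    logger.info("repair: %d cell(s) repaired", count)
    return out, count


def build_forecast_dataset(
    table: pd.DataFrame,
    features: list[str],
    horizon: int,
    include_target_lag: bool = False,
) -> ForecastDataset:
    """Pair features at time i with humidity at time i + horizon."""
    if horizon < 1 or horizon >= len(table):
        raise ValueError("horizon must satisfy 1 <= h < n_rows")
    unknown = [f for f in features if f not in table.columns]
    if unknown:
        raise ValueError(f"unknown feature(s): {unknown}")
    names = list(features)
    X = table[names].iloc[:-horizon].copy()
    if include_target_lag:
        X[synthetic_barn.TARGET_COLUMN] = (
            table[synthetic_barn.TARGET_COLUMN].iloc[:-horizon].to_numpy()
        )
        names = names + [synthetic_barn.TARGET_COLUMN]
    y = table[synthetic_barn.TARGET_COLUMN].iloc[horizon:]
    y = pd.Series(y.to_numpy(), index=X.index, name=synthetic_barn.TARGET_COLUMN)
    return ForecastDataset(X=X, y=y, horizon=horizon, feature_names=names)


def chronological_split(
    dataset: ForecastDataset, train_frac: float = 0.7
) -> tuple[ForecastDataset, ForecastDataset]:
    """First ``floor(train_frac * n)`` rows train, the rest test; no shuffle."""
    n = len(dataset)
    if n < 10:
        raise ValueError("dataset too small to split")
    n_train = int(np.floor(train_frac * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves one side empty")
    mk = lambda sl: ForecastDataset(
        X=dataset.X.iloc[sl],
        y=dataset.y.iloc[sl],
        horizon=dataset.horizon,
        feature_names=dataset.feature_names,
    )
    return mk(slice(0, n_train)), mk(slice(n_train, n))


def _shuffled_split(dataset: ForecastDataset, train_frac: float, seed: int):
    rng = np.random.default_rng(seed)
    n = len(dataset)
    perm = rng.permutation(n)
    n_train = int(np.floor(train_frac * n))
    mk = lambda idx: ForecastDataset(
        X=dataset.X.iloc[np.sort(idx)],
        y=dataset.y.iloc[np.sort(idx)],
        horizon=dataset.horizon,
        feature_names=dataset.feature_names,
    )
    return mk(perm[:n_train]), mk(perm[n_train:])


def _load_table(config: PipelineConfig) -> pd.DataFrame:
    if config.input_csv is not None:
        return pd.read_csv(config.input_csv, index_col="timestamp", parse_dates=True)
    gen = config.generator or synthetic_barn.GeneratorConfig(seed=config.seed)
    return synthetic_barn.generate(gen)


def _evaluate_params(train, test, params, y_params) -> tuple[MetricsReport, np.ndarray]:
    pred = fit_predict_svr(train[0], train[1], test[0], params, target_params=y_params)
    return evaluate(test[2], pred), pred


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all five stages; returns a report dict and writes artifacts
    under ``config.outdir`` when set."""
    try:
        table = _load_table(config)
        table, n_repaired = repair(table)
    except Exception as exc:
        raise RuntimeError(f"stage repair/load failed: {exc}") from exc

    # stage 2: GOSS importance on the training block only
    try:
        full = build_forecast_dataset(
            table, synthetic_barn.FEATURE_COLUMNS, config.horizon, config.include_target_lag
        )
        if config.shuffle_split:
            train_all, test_all = _shuffled_split(full, config.train_frac, config.seed)
        else:
            train_all, test_all = chronological_split(full, config.train_frac)
        goss_cfg = replace(config.goss, seed=config.goss.seed if config.goss.seed is not None else config.seed)
        _, importance = fit_goss_gbdt(
            train_all.X[synthetic_barn.FEATURE_COLUMNS], train_all.y.to_numpy(), goss_cfg
        )
        selected = select_features(importance, config.k_features)
    except Exception as exc:
        raise RuntimeError(f"stage feature-selection failed: {exc}") from exc

    # stage 3: standardize with train-only parameters
    try:
        cols = selected + (
            [synthetic_barn.TARGET_COLUMN] if config.include_target_lag else []
        )
        X_train_raw = train_all.X[cols].to_numpy(dtype=float)
        X_test_raw = test_all.X[cols].to_numpy(dtype=float)
        scaler = Standardizer().fit(X_train_raw, names=cols)
        Xs_train = scaler.transform(X_train_raw)
        Xs_test = scaler.transform(X_test_raw)
        ys_train, y_params = standardize(train_all.y.to_numpy(), name="air_humidity")
        y_test = test_all.y.to_numpy(dtype=float)
    except Exception as exc:
        raise RuntimeError(f"stage standardize/split failed: {exc}") from exc

    # stage 4: hyperparameter search on the training block
    try:
        space = SearchSpace.cube(config.search_lo, config.search_hi, 3)
        objective = make_objective(Xs_train, ys_train, config.fitness)
        result: OptimizeResult = optimize(
            objective,
            space,
            M=config.pack_size,
            nmax=config.max_iter,
            seed=config.seed,
            variant=config.variant,
        )
        best_params = decode_position(result.best_position)
    except Exception as exc:
        raise RuntimeError(f"stage hyperparameter-search failed: {exc}") from exc

    # stage 5: final fit and held-out evaluation in original units
    try:
        train_xyz = (Xs_train, ys_train)
        test_xyz = (Xs_test, None, y_test)
        metrics: dict[str, MetricsReport] = {}
        preds: dict[str, np.ndarray] = {}
        key = f"{config.variant}_svr"
        metrics[key], preds[key] = _evaluate_params(train_xyz, test_xyz, best_params, y_params)
        baseline_params: dict[str, SVRHyperparams] = {}
        if "default_svr" in config.baselines:
            baseline_params["default_svr"] = SVRHyperparams(*DEFAULT_HYPERPARAMS)
        if "gwo_svr" in config.baselines and config.variant != "gwo":
            gwo_res = optimize(
                objective,
                space,
                M=config.pack_size,
                nmax=config.max_iter,
                seed=config.seed,
                variant="gwo",
            )
            baseline_params["gwo_svr"] = decode_position(gwo_res.best_position)
        for name, params in baseline_params.items():
            metrics[name], preds[name] = _evaluate_params(train_xyz, test_xyz, params, y_params)
    except Exception as exc:
        raise RuntimeError(f"stage fit/evaluate failed: {exc}") from exc

    report = {
        "n_repaired": n_repaired,
        "importance": importance,
        "selected_features": selected,
        "best_params": best_params,
        "best_fitness": result.best_fitness,
        "trace": result.trace,
        "metrics": metrics,
        "predictions": preds,
        "actual": y_test,
        "model_key": key,
    }
    if config.outdir is not None:
        _write_artifacts(config, report, result)
    return report


def _metrics_csv(metrics: dict[str, MetricsReport]) -> str:
    lines = ["model,MAE,RMSE,MSE,NRMSE,R2"]
    for name, m in metrics.items():
        d = m.as_dict()
        lines.append(name + "," + ",".join(repr(v) for v in d.values()))
    return "\n".join(lines) + "\n"


def _write_artifacts(config: PipelineConfig, report: dict, result: OptimizeResult) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "importance.csv").write_text(report["importance"].to_csv())
    (outdir / "hyperparams.csv").write_text(report["best_params"].to_csv_row())
    (outdir / "metrics.csv").write_text(_metrics_csv(report["metrics"]))
    (outdir / "trace.csv").write_text(result.trace_csv())
    pred_df = pd.DataFrame({"actual": report["actual"], **report["predictions"]})
    pred_df.to_csv(outdir / "predictions.csv", index=False)
    log_lines = [
        f"seed={config.seed} variant={config.variant} horizon={config.horizon}",
        f"repaired_cells={report['n_repaired']}",
        f"selected_features={','.join(report['selected_features'])}",
        f"best_fitness={report['best_fitness']!r}",
    ] + [f"iter {i}: best_fitness={v!r}" for i, v in enumerate(report["trace"])]
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
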