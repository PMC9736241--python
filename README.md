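# barn-cgwo

Short-horizon forecasting of air humidity in livestock barns from
multivariate 10-minute sensor series. The method combines three pieces:

1. **GOSS-gain feature selection** — gradient-boosted shallow regression
   trees with gradient-based one-side sampling; a feature's importance is
   the sum of its weighted split gains, and the top-k features are kept.
2. **Chaotic grey wolf optimization (CGWO)** — a bound-constrained
   population minimizer in which the canonical random C coefficients are
   replaced by three deterministic iteration-dependent schedules; the plain
   GWO variant is also available.
3. **SVR hyperparameter tuning** — CGWO minimizes forward-chaining
   cross-validated RMSE over the box `[0.01, 10]³` of `(C, g, ε)`, where `g`
   is the RBF *width* (the kernel is `exp(-‖x−x′‖²/g²)`, i.e. gamma `1/g²`).

A synthetic barn-table generator (`barn_cgwo.synthetic_barn`) produces
schema- and range-faithful sensor tables whose humidity is driven, by
construction, by CO₂, light, temperature and PM2.5, so every stage has a
known ground truth without any external data.

## CLI

```sh
# synthesize a 2000-row sensor table
barn-cgwo generate --rows 2000 --seed 1 -o barn.csv

# rank features by GOSS gain on the training block
barn-cgwo importance --input barn.csv --k-features 4

# tune SVR hyperparameters only
barn-cgwo tune --input barn.csv --seed 1

# full pipeline: repair -> select -> standardize/split -> tune -> evaluate
barn-cgwo run --input barn.csv --seed 1 --horizon 10 --outdir results/run1
```

`--horizon` takes 10/30/60/90 (minutes, i.e. 1/3/6/9 steps). A YAML file
passed with `--config` can override any `PipelineConfig` field, e.g.

```yaml
pack_size: 20
max_iter: 20
fitness: {folds: 5}
goss: {n_trees: 50}
```

Artifacts written to `--outdir`: `importance.csv`, `hyperparams.csv`,
`metrics.csv` (tuned model plus baselines), `trace.csv` (best fitness per
iteration), `predictions.csv` and `run.log`.

## Library

```python
from barn_cgwo import GeneratorConfig, PipelineConfig, generate, run_pipeline

report = run_pipeline(PipelineConfig(seed=1))
print(report["selected_features"], report["best_params"])
print(report["metrics"]["cgwo_svr"].as_dict())
```

Runs are pure functions of `(input, config, seed)`: the same seed gives
byte-identical artifacts. All estimated quantities — feature importances,
standardization parameters, hyperparameters — are computed from the
chronological training block only.

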