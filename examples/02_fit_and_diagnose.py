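"""Fit the three model families, select the best, and inspect it.

Cross-validated tuning on the development set, comparison on the
independent test set, then relative influence and a LOESS-smoothed
partial dependence curve for the top predictor.
"""

from croplandn2o import mlcore, obsdata, synthgen
from croplandn2o.mlcore import ModelSpec

table, _ = synthgen.generate_observation_table(n=2186, seed=1)
screened, _ = obsdata.screen_records(table)
features = obsdata.derive_features(screened)
dev, test = obsdata.split_dev_test(features, 0.9, seed=2)

specs = [
    ModelSpec("generalized_linear", cv_folds=10, seed=3),
    ModelSpec("random_forest", grid={"max_features": [0.33, 0.6]},
              cv_folds=10, seed=3, n_estimators=200),
    ModelSpec("boosted_trees",
              grid={"learning_rate": [0.05, 0.1], "max_depth": [3, 5],
                    "subsample": [0.75]},
              cv_folds=10, seed=3),
]
candidates = []
for spec in specs:
    model = mlcore.tune_and_fit(dev, spec)
    metrics = mlcore.evaluate(model, test)
    candidates.append((model, metrics))
    print(f"{spec.family:18s} R2={metrics.r2:.3f} "
          f"RMSE={metrics.rmse:.2f} MAE={metrics.mae:.2f} kg/ha")

best = mlcore.select_best(candidates)
print(f"selected model    : {best.family} {best.hyperparams}")

importance = mlcore.relative_importance(best, dev)
print("top influences (%):")
print(importance.sort_values(ascending=False).head(5).round(1).to_string())

curve = mlcore.partial_dependence(best, dev, "CheN")
print(f"PDP(CheN) rises {curve.smoothed[-1] - curve.smoothed[0]:+.2f} kg/ha "
      f"across the observed range")
# R2 near 0.77 reflects the calibrated signal-to-noise of the
# generator; the boosted family should win on this nonlinear surface.
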