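"""Train the tree-ensemble BUD regressor and predict a single formulation.

The model is trained on the first 80% of records (linear split); the
prediction comes with a standard error derived from per-tree dispersion.
"""

from budcast import (
    FormulationSpec,
    featurize_dataset,
    fit,
    linear_partition,
    load_packaged_dataset,
    predict_grid,
)

ds = load_packaged_dataset()
features = featurize_dataset(ds)
train, test = linear_partition(features, 0.8)
model = fit("tree_ensemble_regression", train, seed=42)
print(f"Trained on {len(train)} records, holding out {len(test)}")

spec = FormulationSpec(
    api=ds.apis["Melatonin"],
    excipients=frozenset({"lactose"}),
    content_pct=10.0,
    temperature_c=25.0,
    packaging="plastic",
)
pred = predict_grid(model, [spec], ds)
row = pred.iloc[0]
print(f"Melatonin 10% in lactose, plastic, 25 degC -> "
      f"BUD {row.bud_days:.0f} +/- {row.stderr_days:.1f} days")
# The point estimate averages 100 regression trees; the +/- is the tree
# standard deviation / sqrt(100), a dispersion (not a calibrated CI).
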