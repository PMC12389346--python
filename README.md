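# budcast

Beyond-use-date (BUD) prediction for compounded oral solid dosage forms.

Hospital and community pharmacies compound capsules and powders when
licensed products are unavailable, but assigning a beyond-use date — the
date after which a preparation must not be used — normally requires
long-term stability studies that are impractical during shortages.
`budcast` is a tabular machine-learning pipeline that estimates BUDs (in
days) for an active pharmaceutical ingredient (API) formulated with one or
two common excipients (lactose, silica, cellulose, mannitol, sucrose,
HPMC), in glass, plastic or paper packaging, across storage temperatures.

The package is aimed at formulation scientists and hospital pharmacists
exploring candidate formulations, and ships a curated dataset of 53
experimental stability records (22 APIs, 6 excipients) collected from the
Stabilis database.

## Method

Every record is encoded as 27 features in three blocks:

1. **API descriptors (18)** — molecular weight (MW), LogP, rotatable bonds
   (RB), polar surface area (PS), H-bond donors/acceptors (HBD/HBA),
   aromatic rings (AR), each paired with an ordinal *class* from a fixed
   binning scheme (MW: 25 classes of 50 g/mol; LogP: 46 classes of 0.5;
   counts: 8 classes of 3; PS: 21 classes of 50 Å²), plus label-encoded
   name/SMILES codes and two composite indices

   * molecule class `MC = MW class + LogP class + RB class`
   * molecular structure class `MSC = PS class + HBD class + HBA class + AR class`

2. **Formulation descriptors (4)** — main-excipient code, a fixed-position
   7-element excipient indicator (e.g. lactose = `[1,0,0,0,0,0,0]`,
   lactose + cellulose = `[1,0,1,0,0,0,0]`), API content (% of unit-dose
   mass) and its 10-level class.

3. **Conditioning/storage descriptors (5)** — packaging code and class
   (glass/plastic/paper = 1/2/3), temperature (°C) and its 15-level class,
   and `storage class = packaging class + content class + temperature class`.

The BUD regressor is a tree-ensemble (100 regression trees, ⌊√p⌋ feature
subsampling per split, bootstrap row sampling), compared against six other
tree-based families (single decision tree, random forests, gradient-boosted
trees, each in classifier and regressor form) on a *linear* 80/20 split —
the first 80 % of rows in file order train, the rest test — scored with
R², MAE, MSE, RMSE, MSD and MAPE. Predictions carry a standard error
(per-tree standard deviation / √100). A grid module enumerates formulation
design spaces (6 pure + 15 binary excipient settings × contents ×
temperatures × packagings) and summarizes predicted BUDs into range
histograms, and a synthetic-data module generates datasets with a known
additive ground truth so parameter recovery can be verified end to end.

## Worked example

```python
>>> from budcast import (load_packaged_dataset, featurize_dataset,
...                      linear_partition, fit, FormulationSpec, predict_grid)
>>> ds = load_packaged_dataset()
>>> train, test = linear_partition(featurize_dataset(ds), 0.8)   # 42 / 11 rows
>>> model = fit("tree_ensemble_regression", train, seed=42)
>>> spec = FormulationSpec(api=ds.apis["Melatonin"], excipients=frozenset({"lactose"}),
...                        content_pct=10.0, temperature_c=25.0, packaging="plastic")
>>> predict_grid(model, [spec], ds).iloc[0]
```

prints (see `examples/02_train_and_predict.py`):

```
Melatonin 10% in lactose, plastic, 25 degC -> BUD 225 +/- 20.3 days
```

i.e. the ensemble estimates a 225-day beyond-use date for 10 % melatonin
in lactose stored at room temperature in plastic, with a 20-day ensemble
dispersion. Composite encodings for melatonin: `MC = 31`, `MSC = 6`
(`examples/01_load_and_encode.py`), matching the printed reference values
for the convention-consistent APIs; a delta report
(`budcast.categorizer.delta_report`) reconciles the APIs whose printed
MC/MSC disagree with any single boundary convention.

The `examples/` directory has one short script per capability: loading and
encoding, training and prediction, family comparison, grid exploration,
and synthetic-data recovery. A thin CLI wraps the same functions:
`budcast validate | featurize | train | evaluate | compare | predict |
grid | simulate` (see `budcast --help`).

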