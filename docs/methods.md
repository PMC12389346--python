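# Methods

## Problem and model

`budcast` regresses the beyond-use date (BUD, days) of a compounded oral
solid preparation on molecular, formulation and storage descriptors. The
target is treated as a continuous quantity; no degradation kinetics,
water-activity or Arrhenius mechanism is modeled — the pipeline is a
purely statistical surrogate trained on experimental stability records,
and its predictions inherit whatever biases the training records carry.

## Ordinal categorization

Continuous and count descriptors are mapped onto 1-based ordinal classes.
The convention, fixed repo-wide, is: class 1 is an open bottom class
("below the lower bound"), interior classes are half-open bins
`[lo, lo + step)`, and the top class is open upward. Scheme catalogue:

| scheme       | classes | class 1 below | step     | top class at/above |
|--------------|---------|---------------|----------|--------------------|
| MW           | 25      | 50 g/mol      | 50 g/mol | 1200 g/mol         |
| LogP         | 46      | −10           | 0.5      | 12                 |
| RB, HBD, HBA, AR | 8   | 3             | 3        | 21                 |
| PS           | 21      | 50 Å²         | 50 Å²    | 1000 Å²            |
| content      | 10      | 10 %          | 10 %     | 90 %               |
| temperature  | 15      | −15 °C        | 5 °C     | 50 °C              |

Packaging is categorical: glass/plastic/paper → class 1/2/3 (listing
order), undocumented → 0. Composite indices are plain sums:
`MC = MW + LogP + RB` classes, `MSC = PS + HBD + HBA + AR` classes
(donors and acceptors contribute separate classes — the alternative, one
combined class, fails to reproduce the reference values),
`storage = packaging + content + temperature` classes. Missing content
contributes class 0 rather than being imputed; silent imputation would
fabricate data that the curated records deliberately leave blank.

This convention reproduces the printed reference MC/MSC for the
convention-consistent APIs (melatonin 31/6, menadione 30/4, captopril
29/6, 4-aminopyridine 24/4, clonidine 33/5, midazolam 38/6). Fifteen of
the 22 packaged APIs have printed values that disagree with *any* single
boundary convention by 1–4; their printed values are stored as reference
columns only and `delta_report` emits the reconciliation instead of the
package guessing per-row intent.

Class assignment uses the arithmetic shortcut `⌊(v − lo)/step⌋ + 2` but
settles the result against the exact edge expressions `lo + step·m`,
because the division can round across an edge for values infinitesimally
below it; a dense-grid property test pins equivalence with a linear edge
scan.

## Feature row

A record encodes to 27 features: 18 API descriptors (raw value + class
pairs, name/SMILES label codes, MC, MSC), 4 formulation descriptors
(main-excipient code, the 7-element excipient indicator counted as one
feature and serialized as a bit string, content % and class) and 5
conditioning/storage descriptors (packaging code and class, temperature
and class, storage class). Label encodings follow first-appearance order
in the dataset, so they are deterministic given file order. In the model
design matrix the indicator expands to 7 binary columns (33 numeric
inputs) and missing content becomes a −1 sentinel that tree splits can
isolate. The indicator's seventh position is reserved and always 0.

## Partitioning and model families

The train/test split is linear: the first `round(0.8 · n)` rows in file
order train (banker's rounding; both sides must be non-empty — 53 rows
give 42/11). Row order is therefore part of the protocol, and the
packaged dataset fixes it to the order the records are printed in
(alphabetical by API).

Seven tree-based families are compared. Regression families fit the BUD
directly; "classifier" families treat each distinct training BUD as one
categorical label and are scored on the numeric day value of the
predicted label, making all seven comparable on regression metrics. The
two forest-style pairs are distinguished by row sampling:
`tree_ensemble_*` uses bootstrap resampling + ⌊√p⌋ feature subsampling
per split (100 trees, unlimited depth, leaf size 1 by default);
`random_forest_*` uses the same feature subsampling without bootstrap.
The single `decision_tree` is a classification tree. Gradient-boosted
families use 100 boosting stages at standard shrinkage. All estimators
are seeded; identical seeds give bit-identical models and predictions.

Prediction standard errors: for averaging ensembles, the sample standard
deviation of per-tree predictions divided by √(tree count) — an ensemble
dispersion, *not* a calibrated confidence interval; single trees and
boosted (additive) ensembles report 0.

## Metrics and correlation screen

R², MAE, MSE, RMSE, MSD and MAPE are computed from their defining
formulas (cross-checked against scikit-learn in the tests). Conventions:
MSD = mean(predicted − observed); MAPE is a proportion. Zero-variance
observations make R² undefined and any observed 0 makes MAPE undefined;
both are signalled with an explicit reason while the remaining metrics
are still returned.

The correlation screen reports the Pearson r of each of the 27 encoded
parameters against a supplied predicted-BUD series, with two-sided
p-values from the t distribution on n − 2 degrees of freedom
(`scipy.stats.pearsonr`), flagging p < 0.05; the excipient indicator
enters as the integer value of its bit vector, and zero-variance
parameters are reported as undefined. No multiple-testing correction is
applied. The prediction set defaults to the held-out rows but any set is
accepted.

A data-vs-narrative note: in the packaged 53-record dataset the observed
LogP–BUD correlation is mildly negative (≈ −0.07), and the screened
correlation of LogP with model predictions is accordingly negative for
every seed. Published summaries of this kind of data disagree internally
on the sign of the LogP association, so the test suite asserts the
internally consistent property — the screened sign matches the observed
sign in the same rows — rather than a fixed sign.

## Held-out performance on the packaged dataset

With the packaged row order, the 11 held-out records are the
alphabetically last APIs, two of which (naltrexone 360 d, nifedipine
365 d) have no close analogues in the 42 training rows. Best-seed
held-out R² for tree-ensemble regression is ≈ 0.51 (10-seed sweep), and
tree-ensemble regression ranks first among the seven families for the
majority of seeds. Substantially higher scores on this split would
require the long-BUD test rows to be predictable from information the
training rows do not contain; users re-ordering the records should
expect split-dependent results, which is why `compare_families` exposes
the seed and the partition fraction.

## Synthetic data and what it shows

The generator emulates the three-table schema with synthetic APIs (MW
log-uniform over 12.01–1461.43 g/mol, LogP uniform over −12.01–17.16,
Poisson-distributed counts) and samples formulations over the six real
excipients (1–2 per record), contents 0.5–100 %, temperatures
{−20, 4, 25, 40} °C and the three packagings. BUD follows an additive
linear truth — intercept 180 d, LogP effect −10 d/unit, excipient offsets
(cellulose +20, silica +15, sucrose +15, mannitol +10, lactose −25, HPMC
−30 d), temperature −2 d/°C from 25 °C, content −0.5 d/% — plus Gaussian
noise (sd 5 d), clipped at 1 day. The offsets and signs mirror the
qualitative structure reported for real preparations (hygroscopic
lactose/HPMC destabilize; lower LogP and colder storage stabilize); the
linear form is chosen because it makes recovery assertions sharp, not
because real degradation is linear. Clipping distorts the truth near
zero and is documented as such.

`recovery_report` retrains the tree-ensemble regressor on generated data
and reports held-out R², the sign of the predicted-BUD-vs-LogP trend, and
the Spearman rank agreement between injected excipient offsets and mean
predicted BUD per pure excipient on a controlled probe grid (same APIs,
fixed content/temperature/packaging, only the excipient varying — a
design that isolates the excipient effect from API composition). With the
default truth at n = 500 the pipeline reaches held-out R² ≈ 0.94,
recovers the negative LogP trend, and ranks the excipient offsets at
ρ ≈ 0.9; a pure-noise truth yields R² ≈ 0. Passing these checks shows the
*pipeline* is sound — an additive truth this clean says nothing about how
well 53 heterogeneous real records constrain a forest.

## Numerical and design choices

* Sizes used by default: 100 trees; 10-seed sweeps for best-seed
  reporting; synthetic runs at n = 500 (recovery) chosen so the full
  suite runs comfortably on a laptop-class single core.
* Round-half-to-even in the linear partition; ≥ 1 row enforced on each side.
* Model persistence via joblib with a format-version field; round-trip
  equality of predictions is tested. The byte format is
  implementation-defined.
* Excipient names are canonicalized to lowercase at load; display names
  are preserved separately. Sentinels `ND`/`-` become `None`, never 0.
* Dose (mg) is retained in the data model but excluded from the feature
  row; content % is the modeled quantity.
* The grid module's default temperature set is {4, 25, 40} °C and default
  histogram edges 80/120/140/150/160/170 days; both configurable.

## Limitations

* 53 records spanning 22 APIs is a very small training base; held-out
  metrics are dominated by which APIs fall in the test block.
* Classifier families can only predict BUD values seen in training.
* Ensemble standard errors are dispersions, not calibrated intervals.
* The synthetic generator does not simulate degradation kinetics,
  moisture exchange, polymorphism or excipient interaction terms.
* SMILES strings are opaque identifiers; no descriptor computation is
  performed (descriptors are inputs).
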