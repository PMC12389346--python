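"""Tree-based BUD regression: partitioning, the seven model families, prediction.

The train/test split is *linear*: the first ``round(fraction * n)`` rows in
file order form the training set, the remainder the test set (no shuffling
— row order is part of the experimental protocol).

Seven model families are supported.  Families whose name carries the
``_regression`` suffix (plus the plain regression tree inside
``decision_tree``'s regression counterpart) regress directly on BUD in
days; "classifier" families treat each distinct training BUD value as a
categorical label and are nevertheless scored on the numeric day value of
the predicted label, so all seven are comparable on regression metrics.

For averaging ensembles the prediction standard error is the sample
standard deviation of per-tree predictions divided by √(tree count);
single trees and boosted (additive) ensembles report 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.tree import DecisionTreeClassifier

from .categorizer import FEATURE_COLUMNS

__all__ = [
    "MODEL_FAMILIES",
    "Hyperparameters",
    "EnsembleModel",
    "BUDPrediction",
    "PartitionError",
    "FitError",
    "SchemaMismatchError",
    "linear_partition",
    "to_matrix",
    "fit",
    "predict",
    "predict_batch",
    "save_model",
    "load_model",
]

#: The closed set of model families (one per comparison-table column).
MODEL_FAMILIES = (
    "decision_tree",
    "random_forest_classifier",
    "random_forest_regression",
    "tree_ensemble_classifier",
    "tree_ensemble_regression",
    "gradient_boosted_trees_classifier",
    "gradient_boosted_trees_regression",
)

#: Sentinel used for missing numeric feature values in the design matrix
#: (tree models split on it; nothing is imputed).
MISSING_SENTINEL = -1.0

_INDICATOR_COLUMNS = [f"exc_{i}" for i in range(7)]


class PartitionError(ValueError):
    """The requested linear partition is infeasible."""


class FitError(ValueError):
    """Training failed (e.g. empty training set, unknown family)."""


class SchemaMismatchError(ValueError):
    """Prediction-time features do not match the model's feature schema."""


@dataclass(frozen=True)
class Hyperparameters:
    """Ensemble hyperparameters; defaults follow common random-forest practice.

    ``max_features`` is the per-split feature-subsampling rule ("sqrt" =
    ⌊√p⌋ features per split, 1.0 = all features); ``bootstrap`` toggles
    per-tree row resampling.
    """

    n_trees: int = 100
    max_features: str | float = "sqrt"
    bootstrap: bool = True
    max_depth: int | None = None
    min_samples_leaf: int = 1


@dataclass
class EnsembleModel:
    """A fitted model with its family, seed, hyperparameters and feature schema."""

    family: str
    estimator: object
    hyperparameters: Hyperparameters
    seed: int
    feature_schema: list[str]
    target_range: tuple[float, float]
    label_values: np.ndarray | None = None  # day value of each class label, classifiers only

    @property
    def is_averaging_ensemble(self) -> bool:
        return self.family in (
            "random_forest_classifier",
            "random_forest_regression",
            "tree_ensemble_classifier",
            "tree_ensemble_regression",
        )


@dataclass(frozen=True)
class BUDPrediction:
    """Point BUD estimate in days with an ensemble-dispersion standard error."""

    bud_days: float
    stderr_days: float
    per_tree: np.ndarray | None = None


def linear_partition(rows: pd.DataFrame, train_fraction: float = 0.8) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split rows into (train, test) by taking the first rows in order.

    The training size is ``round(train_fraction * n)`` (banker's rounding).
    Both sides must be non-empty.
    """
    if not 0 < train_fraction < 1:
        raise PartitionError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(rows)
    if n < 2:
        raise PartitionError(f"need at least 2 rows to partition, got {n}")
    n_train = round(train_fraction * n)
    if n_train < 1 or n - n_train < 1:
        raise PartitionError(
            f"partition of {n} rows at fraction {train_fraction} leaves an empty side "
            f"({n_train} train / {n - n_train} test); at least 1 row is required on each"
        )
    return rows.iloc[:n_train].copy(), rows.iloc[n_train:].copy()


def to_matrix(rows: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Expand feature rows into the numeric design matrix.

    The 7-character ``excipient_vector`` bit string becomes 7 binary
    columns; missing ``content_pct`` becomes the -1 sentinel.  Returns the
    matrix and the ordered column names (the model's feature schema).
    """
    missing = [c for c in FEATURE_COLUMNS if c not in rows.columns]
    if missing:
        raise SchemaMismatchError(f"missing feature column(s): {missing}")
    out = rows.loc[:, list(FEATURE_COLUMNS)].copy()
    vec = out.pop("excipient_vector").astype(str)
    for i, col in enumerate(_INDICATOR_COLUMNS):
        out[col] = vec.str.slice(i, i + 1).astype(int)
    out["content_pct"] = pd.to_numeric(out["content_pct"]).fillna(MISSING_SENTINEL)
    schema = list(out.columns)
    return out.to_numpy(dtype=float), schema


def _make_estimator(family: str, hp: Hyperparameters, seed: int):
    common = dict(
        n_estimators=hp.n_trees,
        max_depth=hp.max_depth,
        min_samples_leaf=hp.min_samples_leaf,
        random_state=seed,
    )
    if family == "decision_tree":
        return DecisionTreeClassifier(
            max_depth=hp.max_depth, min_samples_leaf=hp.min_samples_leaf, random_state=seed
        )
    if family == "random_forest_regression":
        return RandomForestRegressor(max_features=hp.max_features, bootstrap=False, **common)
    if family == "tree_ensemble_regression":
        return RandomForestRegressor(max_features=hp.max_features, bootstrap=hp.bootstrap, **common)
    if family == "random_forest_classifier":
        return RandomForestClassifier(max_features=hp.max_features, bootstrap=False, **common)
    if family == "tree_ensemble_classifier":
        return RandomForestClassifier(max_features=hp.max_features, bootstrap=hp.bootstrap, **common)
    if family == "gradient_boosted_trees_regression":
        return GradientBoostingRegressor(n_estimators=hp.n_trees, random_state=seed)
    if family == "gradient_boosted_trees_classifier":
        return GradientBoostingClassifier(n_estimators=hp.n_trees, random_state=seed)
    raise FitError(f"unknown model family {family!r}; expected one of {MODEL_FAMILIES}")


def _is_classifier_family(family: str) -> bool:
    return family in (
        "decision_tree",
        "random_forest_classifier",
        "tree_ensemble_classifier",
        "gradient_boosted_trees_classifier",
    )


def fit(
    family: str,
    train_rows: pd.DataFrame,
    seed: int = 42,
    hyperparameters: Hyperparameters | None = None,
) -> EnsembleModel:
    """Train one model family on featurized rows carrying ``bud_days``.

    Deterministic given (rows, seed, hyperparameters).  Classifier families
    use each distinct training BUD as one label and decode predictions back
    to days.
    """
    if len(train_rows) == 0:
        raise FitError("training set is empty")
    if "bud_days" not in train_rows.columns or train_rows["bud_days"].isna().any():
        raise FitError("every training row must carry a bud_days target")
    hp = hyperparameters or Hyperparameters()
    X, schema = to_matrix(train_rows)
    y = train_rows["bud_days"].to_numpy(dtype=float)
    est = _make_estimator(family, hp, seed)
    label_values = None
    if _is_classifier_family(family):
        label_values, y_enc = np.unique(y, return_inverse=True)
        if len(label_values) == 1 and family == "gradient_boosted_trees_classifier":
            # boosting needs >= 2 classes; a single tree reproduces the constant
            est = DecisionTreeClassifier(random_state=seed)
        est.fit(X, y_enc)
    else:
        est.fit(X, y)
    return EnsembleModel(
        family=family,
        estimator=est,
        hyperparameters=hp,
        seed=seed,
        feature_schema=schema,
        target_range=(float(y.min()), float(y.max())),
        label_values=label_values,
    )


def _decode(model: EnsembleModel, raw: np.ndarray) -> np.ndarray:
    if model.label_values is None:
        return raw
    return model.label_values[raw.astype(int)]


def _per_tree_predictions(model: EnsembleModel, X: np.ndarray) -> np.ndarray | None:
    """(n_trees, n_rows) member predictions in days, for averaging ensembles."""
    est = model.estimator
    if not model.is_averaging_ensemble or not hasattr(est, "estimators_"):
        return None
    per_tree = np.stack([t.predict(X) for t in est.estimators_])
    if model.label_values is not None:
        per_tree = model.label_values[per_tree.astype(int)]
    return per_tree


def predict_batch(model: EnsembleModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Predict BUD for many feature rows at once.

    Returns a DataFrame with ``bud_days`` and ``stderr_days`` columns,
    index-aligned with ``rows``.
    """
    X, schema = to_matrix(rows)
    if schema != model.feature_schema:
        extra = set(schema) - set(model.feature_schema)
        missing = set(model.feature_schema) - set(schema)
        raise SchemaMismatchError(
            f"feature schema mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
        )
    point = _decode(model, np.asarray(model.estimator.predict(X), dtype=float))
    per_tree = _per_tree_predictions(model, X)
    if per_tree is None or per_tree.shape[0] < 2:
        stderr = np.zeros(len(point))
    else:
        stderr = per_tree.std(axis=0, ddof=1) / np.sqrt(per_tree.shape[0])
    # classifier point estimate = majority label; averaging regressors = tree mean
    return pd.DataFrame({"bud_days": point, "stderr_days": stderr}, index=rows.index)


def predict(model: EnsembleModel, row: pd.Series | dict) -> BUDPrediction:
    """Predict BUD for a single feature row."""
    frame = pd.DataFrame([row])
    X, schema = to_matrix(frame)
    if schema != model.feature_schema:
        missing = set(model.feature_schema) - set(schema)
        extra = set(schema) - set(model.feature_schema)
        raise SchemaMismatchError(
            f"feature schema mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
        )
    out = predict_batch(model, frame)
    per_tree = _per_tree_predictions(model, X)
    return BUDPrediction(
        bud_days=float(out["bud_days"].iloc[0]),
        stderr_days=float(out["stderr_days"].iloc[0]),
        per_tree=None if per_tree is None else per_tree[:, 0],
    )


_FORMAT_VERSION = 1


def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Persist a fitted model (self-describing, versioned)."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "family": model.family,
        "hyperparameters": model.hyperparameters,
        "seed": model.seed,
        "feature_schema": model.feature_schema,
        "target_range": model.target_range,
        "label_values": model.label_values,
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> EnsembleModel:
    payload = joblib.load(path)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {payload.get('format_version')!r}")
    return EnsembleModel(
        family=payload["family"],
        estimator=payload["estimator"],
        hyperparameters=payload["hyperparameters"],
        seed=payload["seed"],
        feature_schema=payload["feature_schema"],
        target_range=tuple(payload["target_range"]),
        label_values=payload["label_values"],
    )
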