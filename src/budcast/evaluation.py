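"""Model evaluation: six regression metrics, family comparison, correlation screen.

Metrics (all computed on held-out rows, in days unless noted):

* R²    = 1 − Σ(o − p)² / Σ(o − ō)²
* MAE   = mean |p − o|
* MSE   = mean (p − o)²            (days²)
* RMSE  = √MSE
* MSD   = mean (p − o)             (sign convention: predicted − observed)
* MAPE  = mean |p − o| / |o|       (proportion, not percent)

Degenerate situations are signalled explicitly instead of leaking NaN:
zero-variance observations make R² undefined; any observed value of 0
makes MAPE undefined; the remaining metrics are still returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .amf_db import CuratedDataset
from .categorizer import FEATURE_COLUMNS, featurize_dataset
from .regressor import (
    MODEL_FAMILIES,
    Hyperparameters,
    fit,
    linear_partition,
    predict_batch,
)

__all__ = [
    "MetricReport",
    "CorrelationRow",
    "compute_metrics",
    "compare_families",
    "correlation_screen",
]


@dataclass(frozen=True)
class MetricReport:
    """The six evaluation statistics.  ``None`` marks an undefined metric."""

    r2: float | None
    mae: float
    mse: float
    rmse: float
    msd: float
    mape: float | None
    n: int
    degenerate_reason: str | None = None


def compute_metrics(predicted, observed) -> MetricReport:
    """Compute the six-metric report for paired day series of equal length ≥ 2."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: predicted {p.shape} vs observed {o.shape}")
    if p.ndim != 1 or len(p) < 2:
        raise ValueError("need 1-d series of length >= 2")
    err = p - o
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    msd = float(np.mean(err))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    degenerate = None
    if ss_tot == 0.0:
        r2 = None
        degenerate = "observed series has zero variance; R^2 undefined"
    else:
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    if np.any(o == 0):
        mape = None
        degenerate = (degenerate + "; " if degenerate else "") + "observed value of 0; MAPE undefined"
    else:
        mape = float(np.mean(np.abs(err) / np.abs(o)))
    return MetricReport(
        r2=r2, mae=mae, mse=mse, rmse=float(np.sqrt(mse)), msd=msd, mape=mape,
        n=len(p), degenerate_reason=degenerate,
    )


def compare_families(
    ds: CuratedDataset,
    seed: int = 42,
    train_fraction: float = 0.8,
    hyperparameters: Hyperparameters | None = None,
    families: tuple[str, ...] = MODEL_FAMILIES,
) -> pd.DataFrame:
    """Fit every model family on the linear 80/20 split and score the held-out rows.

    Returns one row per family with the six metrics (columns ``r2``,
    ``mae``, ``mse``, ``rmse``, ``msd``, ``mape``).  A family whose fit or
    prediction fails is kept in the table with an ``error`` note rather
    than aborting the comparison.
    """
    features = featurize_dataset(ds)
    train, test = linear_partition(features, train_fraction)
    rows = []
    for family in families:
        try:
            model = fit(family, train, seed=seed, hyperparameters=hyperparameters)
            pred = predict_batch(model, test)
            report = compute_metrics(pred["bud_days"], test["bud_days"])
            rows.append(
                {
                    "family": family, "r2": report.r2, "mae": report.mae,
                    "mse": report.mse, "rmse": report.rmse, "msd": report.msd,
                    "mape": report.mape, "n_test": report.n, "error": None,
                }
            )
        except Exception as exc:  # noqa: BLE001 — failed cells are reported, not fatal
            rows.append(
                {
                    "family": family, "r2": None, "mae": None, "mse": None,
                    "rmse": None, "msd": None, "mape": None, "n_test": None,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows).set_index("family")


@dataclass(frozen=True)
class CorrelationRow:
    """Pearson correlation of one encoded parameter with predicted BUD."""

    parameter: str
    r: float | None
    p: float | None
    significant: bool | None  # p < 0.05

    @property
    def undefined(self) -> bool:
        return self.r is None


def _numeric_parameter(features: pd.DataFrame, column: str) -> np.ndarray:
    values = features[column]
    if column == "excipient_vector":
        # the 7-bit indicator as one ordinal parameter (integer value of the bits)
        return values.astype(str).apply(lambda s: int(s, 2)).to_numpy(dtype=float)
    return pd.to_numeric(values).fillna(-1.0).to_numpy(dtype=float)


def correlation_screen(features: pd.DataFrame, predicted) -> list[CorrelationRow]:
    """Pearson r (and two-sided t-test p-value, n−2 df) of each of the 27
    encoded parameters against a predicted-BUD series.

    Zero-variance parameters are reported as undefined rather than NaN.
    """
    y = np.asarray(predicted, dtype=float)
    if len(features) != len(y):
        raise ValueError(f"length mismatch: {len(features)} feature rows vs {len(y)} predictions")
    if len(y) < 3:
        raise ValueError("need at least 3 rows for a correlation screen")
    out = []
    for column in FEATURE_COLUMNS:
        x = _numeric_parameter(features, column)
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            out.append(CorrelationRow(parameter=column, r=None, p=None, significant=None))
            continue
        r, p = stats.pearsonr(x, y)
        out.append(
            CorrelationRow(parameter=column, r=float(r), p=float(p), significant=bool(p < 0.05))
        )
    return out


def correlation_table(rows: list[CorrelationRow]) -> pd.DataFrame:
    """Tidy DataFrame view of a correlation screen."""
    return pd.DataFrame(
        [
            {"parameter": c.parameter, "r": c.r, "p": c.p, "significant": c.significant}
            for c in rows
        ]
    )
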