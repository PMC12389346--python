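"""Formulation design-space exploration.

Enumerates candidate formulations (API × excipient setting × content ×
temperature × packaging), runs batch BUD predictions with a trained
ensemble, and summarizes predictions into BUD-range frequency histograms.

Excipient settings: "pure" = each of the 6 single excipients; "binary" =
each of the C(6,2) = 15 unordered pairs; "both" = all 21.  The default
content grid is {1, 10, 50, 90} % and the default temperature grid
{4, 25, 40} °C (15 °C can be configured in as well); default histogram
edges are 80/120/140/150/160/170 days.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .amf_db import EXCIPIENT_NAMES, APIDescriptorRecord, CuratedDataset, StabilityRecord
from .categorizer import _LabelCodes, featurize
from .regressor import EnsembleModel, predict_batch

__all__ = [
    "DEFAULT_CONTENTS",
    "DEFAULT_TEMPERATURES",
    "DEFAULT_EDGES",
    "FormulationSpec",
    "enumerate_formulations",
    "predict_grid",
    "bud_histogram",
]

DEFAULT_CONTENTS: Sequence[float] = (1.0, 10.0, 50.0, 90.0)
DEFAULT_TEMPERATURES: Sequence[float] = (4.0, 25.0, 40.0)
DEFAULT_PACKAGINGS: Sequence[str] = ("glass", "plastic", "paper")
DEFAULT_EDGES: Sequence[float] = (80.0, 120.0, 140.0, 150.0, 160.0, 170.0)


@dataclass(frozen=True)
class FormulationSpec:
    """One candidate formulation scenario to be scored."""

    api: APIDescriptorRecord
    excipients: frozenset[str]
    content_pct: float
    temperature_c: float
    packaging: str

    def __post_init__(self) -> None:
        if not 1 <= len(self.excipients) <= 2:
            raise ValueError(f"need 1-2 excipients, got {sorted(self.excipients)}")


def _excipient_settings(mode: str) -> list[tuple[str, ...]]:
    pure = [(e,) for e in EXCIPIENT_NAMES]
    binary = [tuple(sorted(pair)) for pair in combinations(EXCIPIENT_NAMES, 2)]
    binary.sort()
    if mode == "pure":
        return pure
    if mode == "binary":
        return binary
    if mode == "both":
        return sorted(pure) + binary
    raise ValueError(f"excipient_mode must be 'pure', 'binary' or 'both', got {mode!r}")


def enumerate_formulations(
    apis: Iterable[APIDescriptorRecord],
    contents: Sequence[float] = DEFAULT_CONTENTS,
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    packagings: Sequence[str] = DEFAULT_PACKAGINGS,
    excipient_mode: str = "both",
) -> list[FormulationSpec]:
    """Deterministic lexicographic enumeration of the formulation grid.

    Pure mode yields 6 settings per (api, content, temperature, packaging)
    cell, binary 15, both 21.
    """
    apis = list(apis)
    if not apis or not contents or not temperatures or not packagings:
        raise ValueError("all enumeration grids must be non-empty")
    settings = _excipient_settings(excipient_mode)
    specs = []
    for api, exc, content, temp, pack in product(
        apis, settings, contents, temperatures, packagings
    ):
        specs.append(
            FormulationSpec(
                api=api,
                excipients=frozenset(exc),
                content_pct=float(content),
                temperature_c=float(temp),
                packaging=pack,
            )
        )
    return specs


def _spec_record(spec: FormulationSpec) -> StabilityRecord:
    excs = sorted(spec.excipients)
    return StabilityRecord(
        api_name=spec.api.name,
        main_excipient=excs[0],
        other_excipient=excs[1] if len(excs) > 1 else None,
        packaging=spec.packaging,
        dose_mg=None,
        content_pct=spec.content_pct,
        temperature_c=spec.temperature_c,
        bud_days=1.0,  # placeholder target, dropped before prediction
    )


def predict_grid(
    model: EnsembleModel, specs: Sequence[FormulationSpec], ds: CuratedDataset
) -> pd.DataFrame:
    """Score every formulation spec with the trained model.

    ``ds`` supplies the label-encoding context (name/SMILES codes are
    first-appearance codes over the training dataset, extended
    deterministically for unseen APIs).  Returns one row per spec with the
    spec identifiers, ``bud_days`` and ``stderr_days``.
    """
    if not specs:
        raise ValueError("no formulation specs to predict")
    codes = _LabelCodes(ds)
    ds_apis = dict(ds.apis)
    rows = []
    meta = []
    for spec in specs:
        ds_apis.setdefault(spec.api.name, spec.api)
        rec = _spec_record(spec)
        local = CuratedDataset(apis=ds_apis, excipients=ds.excipients, records=[rec])
        row = featurize(rec, local, codes)
        row.pop("bud_days")
        rows.append(row)
        meta.append(
            {
                "api": spec.api.name,
                "excipients": "+".join(sorted(spec.excipients)),
                "content_pct": spec.content_pct,
                "temperature_c": spec.temperature_c,
                "packaging": spec.packaging,
            }
        )
    features = pd.DataFrame(rows)
    pred = predict_batch(model, features)
    out = pd.DataFrame(meta)
    out["bud_days"] = pred["bud_days"].to_numpy()
    out["stderr_days"] = pred["stderr_days"].to_numpy()
    return out


def bud_histogram(
    predictions: pd.DataFrame,
    edges: Sequence[float] = DEFAULT_EDGES,
    group_columns: Sequence[str] = ("excipients", "content_pct", "temperature_c"),
) -> pd.DataFrame:
    """Bin predicted BUDs into half-open ranges ``[e_i, e_{i+1})`` per group.

    Values outside ``[e_0, e_last)`` land in explicit underflow/overflow
    bins.  Returns a tidy frame with group columns, ``bin``, ``count`` and
    ``percent``; per-group percentages sum to 100.
    """
    edges = list(edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError(f"edges must be strictly increasing with >= 2 entries, got {edges}")
    group_columns = [c for c in group_columns if c in predictions.columns]
    labels = (
        [f"<{edges[0]:g}"]
        + [f"[{a:g},{b:g})" for a, b in zip(edges, edges[1:])]
        + [f">={edges[-1]:g}"]
    )

    def _bin_group(values: np.ndarray) -> pd.DataFrame:
        idx = np.searchsorted(edges, values, side="right")  # 0 = underflow
        counts = np.bincount(idx, minlength=len(labels))
        return pd.DataFrame(
            {
                "bin": labels,
                "count": counts,
                "percent": 100.0 * counts / len(values),
            }
        )

    if not group_columns:
        return _bin_group(predictions["bud_days"].to_numpy(dtype=float))
    parts = []
    for keys, sub in predictions.groupby(list(group_columns), sort=True):
        part = _bin_group(sub["bud_days"].to_numpy(dtype=float))
        if not isinstance(keys, tuple):
            keys = (keys,)
        for col, key in zip(group_columns, keys):
            part.insert(0, col, key)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)
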