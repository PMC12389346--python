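"""Descriptor categorization and feature encoding for BUD modeling.

Every continuous or count descriptor is mapped onto an ordinal class scale:
class 1 is an open bottom class ("below the lower bound"), interior classes
are half-open bins ``[lo, hi)`` of fixed width, and the top class is open
upward.  Three composite indices summarize groups of classes:

* MC  (molecule class)            = MW class + LogP class + RB class
* MSC (molecular structure class) = PS class + HBD class + HBA class + AR class
* storage class                   = packaging class + content class + temperature class

Excipient composition is a fixed-position 7-element binary indicator
(lactose, silica, cellulose, mannitol, sucrose, hpmc, reserved).  A full
encoded observation is a 27-feature row (18 API + 4 formulation + 5
conditioning/storage features, the indicator counting as one feature) plus
the BUD target when known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .amf_db import (
    EXCIPIENT_NAMES,
    APIDescriptorRecord,
    CuratedDataset,
    StabilityRecord,
)

__all__ = [
    "BinningScheme",
    "SCHEMES",
    "PACKAGING_CLASS",
    "FEATURE_COLUMNS",
    "assign_class",
    "encode_excipients",
    "molecule_class",
    "molecular_structure_class",
    "storage_class",
    "featurize",
    "featurize_dataset",
    "delta_report",
]


@dataclass(frozen=True)
class BinningScheme:
    """An ordinal binning of the real line into ``class_count`` classes.

    ``lower_open_bound`` is the threshold below which class 1 applies;
    interior classes have width ``step``; the top class is open upward.
    """

    name: str
    class_count: int
    lower_open_bound: float
    step: float

    def assign(self, value: float) -> int:
        return assign_class(value, self)

    def edges(self) -> list[float]:
        """The class boundaries (length ``class_count - 1``)."""
        return [self.lower_open_bound + self.step * k for k in range(self.class_count - 1)]


def assign_class(value: float, scheme: BinningScheme) -> int:
    """Map ``value`` to its 1-based class index under ``scheme``.

    Class 1 iff ``value < lower_open_bound``; the top class is open; interior
    bins are half-open ``[lo, hi)``.  Non-finite values are rejected.
    """
    if not math.isfinite(value):
        raise ValueError(f"scheme {scheme.name!r}: value must be finite, got {value!r}")
    lb, step, K = scheme.lower_open_bound, scheme.step, scheme.class_count
    if value < lb:
        return 1
    k = min(int(math.floor((value - lb) / step)) + 2, K)
    # the division can round across a bin edge for values infinitesimally
    # close to it; settle against the exact edge expressions lb + step*m
    while k > 1 and value < lb + step * (k - 2):
        k -= 1
    while k < K and value >= lb + step * (k - 1):
        k += 1
    return k


def _count_scheme(name: str) -> BinningScheme:
    # counts: class 1 = {0,1,2}, then steps of three, class 8 = 21+
    return BinningScheme(name=name, class_count=8, lower_open_bound=3, step=3)


#: The fixed scheme catalogue.  Cardinalities: MW 25, LogP 46, RB 8, PS 21,
#: HBD 8, HBA 8, AR 8, content 10, temperature 15 (packaging is a 3-type
#: categorical handled by :data:`PACKAGING_CLASS`).
SCHEMES: Mapping[str, BinningScheme] = {
    "mw": BinningScheme("mw", class_count=25, lower_open_bound=50.0, step=50.0),
    "logp": BinningScheme("logp", class_count=46, lower_open_bound=-10.0, step=0.5),
    "rb": _count_scheme("rb"),
    "ps": BinningScheme("ps", class_count=21, lower_open_bound=50.0, step=50.0),
    "hbd": _count_scheme("hbd"),
    "hba": _count_scheme("hba"),
    "ar": _count_scheme("ar"),
    "content": BinningScheme("content", class_count=10, lower_open_bound=10.0, step=10.0),
    "temperature": BinningScheme("temperature", class_count=15, lower_open_bound=-15.0, step=5.0),
}

#: Packaging classes follow the listing order glass, plastic, paper;
#: undocumented packaging contributes 0.
PACKAGING_CLASS: Mapping[str | None, int] = {"glass": 1, "plastic": 2, "paper": 3, None: 0}

#: Fixed positions of the excipient indicator (last slot reserved).
INDICATOR_POSITIONS: Sequence[str] = EXCIPIENT_NAMES  # + 1 reserved trailing slot


def encode_excipients(excipients: Iterable[str]) -> tuple[int, ...]:
    """Encode 0–2 excipient names as the fixed-position 7-element indicator.

    Order-insensitive; e.g. ``{"lactose"}`` → ``(1, 0, 0, 0, 0, 0, 0)`` and
    ``{"lactose", "cellulose"}`` → ``(1, 0, 1, 0, 0, 0, 0)``.
    """
    indicator = [0] * 7
    for name in set(excipients):
        try:
            indicator[INDICATOR_POSITIONS.index(name)] = 1
        except ValueError:
            raise ValueError(f"unknown excipient {name!r}; expected one of {tuple(INDICATOR_POSITIONS)}") from None
    return tuple(indicator)


def molecule_class(api: APIDescriptorRecord) -> int:
    """MC = MW class + LogP class + RB class."""
    return (
        assign_class(api.mw, SCHEMES["mw"])
        + assign_class(api.logp, SCHEMES["logp"])
        + assign_class(api.rb, SCHEMES["rb"])
    )


def molecular_structure_class(api: APIDescriptorRecord) -> int:
    """MSC = PS class + HBD class + HBA class + AR class."""
    return (
        assign_class(api.ps, SCHEMES["ps"])
        + assign_class(api.hbd, SCHEMES["hbd"])
        + assign_class(api.hba, SCHEMES["hba"])
        + assign_class(api.ar, SCHEMES["ar"])
    )


def storage_class(
    packaging: str | None, content_pct: float | None, temperature_c: float
) -> int:
    """Storage class = packaging class + content class + temperature class.

    Undocumented packaging and missing content each contribute 0 (no
    imputation).
    """
    if packaging not in PACKAGING_CLASS:
        raise ValueError(f"unknown packaging {packaging!r}")
    content_class = 0 if content_pct is None else assign_class(content_pct, SCHEMES["content"])
    return (
        PACKAGING_CLASS[packaging]
        + content_class
        + assign_class(temperature_c, SCHEMES["temperature"])
    )


#: The 27 feature columns, in schema order (plus ``bud_days`` when known).
FEATURE_COLUMNS: Sequence[str] = (
    # 18 API descriptors
    "name_code", "smiles_code",
    "mw", "mw_class", "logp", "logp_class", "rb", "rb_class",
    "ps", "ps_class", "hbd", "hbd_class", "hba", "hba_class",
    "ar", "ar_class", "mc", "msc",
    # 4 formulation descriptors
    "main_excipient_code", "excipient_vector", "content_pct", "content_class",
    # 5 conditioning/storage descriptors
    "packaging_code", "packaging_class", "temperature_c", "temperature_class",
    "storage_class",
)


class _LabelCodes:
    """First-appearance-order label encoding over the dataset (deterministic
    given file order)."""

    def __init__(self, ds: CuratedDataset):
        self.name_code = {name: i for i, name in enumerate(ds.apis)}
        self.smiles_code: dict[str, int] = {}
        for api in ds.apis.values():
            self.smiles_code.setdefault(api.smiles, len(self.smiles_code))
        self.main_excipient_code: dict[str | None, int] = {}
        self.packaging_code: dict[str | None, int] = {}
        for rec in ds.records:
            self.main_excipient_code.setdefault(rec.main_excipient, len(self.main_excipient_code))
            self.packaging_code.setdefault(rec.packaging, len(self.packaging_code))

    def code(self, table: dict, key, label: str) -> int:
        if key not in table:
            table[key] = len(table)  # unseen level: extend deterministically
        return table[key]


def featurize(
    record: StabilityRecord, ds: CuratedDataset, codes: _LabelCodes | None = None
) -> dict:
    """Encode one stability record as the 27-feature row (+ ``bud_days``).

    API name and SMILES are label-encoded by first appearance order in
    ``ds``; the excipient indicator is serialized as a 7-character bit
    string (one feature).
    """
    if codes is None:
        codes = _LabelCodes(ds)
    api = ds.api_for(record)
    s = SCHEMES
    indicator = encode_excipients(record.excipients)
    content_class = (
        0 if record.content_pct is None else assign_class(record.content_pct, s["content"])
    )
    row = {
        "name_code": codes.code(codes.name_code, api.name, "name"),
        "smiles_code": codes.code(codes.smiles_code, api.smiles, "smiles"),
        "mw": api.mw, "mw_class": assign_class(api.mw, s["mw"]),
        "logp": api.logp, "logp_class": assign_class(api.logp, s["logp"]),
        "rb": api.rb, "rb_class": assign_class(api.rb, s["rb"]),
        "ps": api.ps, "ps_class": assign_class(api.ps, s["ps"]),
        "hbd": api.hbd, "hbd_class": assign_class(api.hbd, s["hbd"]),
        "hba": api.hba, "hba_class": assign_class(api.hba, s["hba"]),
        "ar": api.ar, "ar_class": assign_class(api.ar, s["ar"]),
        "mc": molecule_class(api),
        "msc": molecular_structure_class(api),
        "main_excipient_code": codes.code(
            codes.main_excipient_code, record.main_excipient, "main_excipient"
        ),
        "excipient_vector": "".join(str(b) for b in indicator),
        "content_pct": record.content_pct,
        "content_class": content_class,
        "packaging_code": codes.code(codes.packaging_code, record.packaging, "packaging"),
        "packaging_class": PACKAGING_CLASS[record.packaging],
        "temperature_c": record.temperature_c,
        "temperature_class": assign_class(record.temperature_c, s["temperature"]),
        "storage_class": storage_class(record.packaging, record.content_pct, record.temperature_c),
        "bud_days": record.bud_days,
    }
    return row


def featurize_dataset(ds: CuratedDataset) -> pd.DataFrame:
    """Encode every stability record; rows keep dataset order.

    Returns a DataFrame with the 27 feature columns plus ``bud_days``.
    """
    codes = _LabelCodes(ds)
    rows = [featurize(rec, ds, codes) for rec in ds.records]
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS) + ["bud_days"])


def delta_report(ds: CuratedDataset) -> pd.DataFrame:
    """Computed-vs-printed MC/MSC per API.

    The packaged descriptor tables carry the source's printed composite
    classes as reference columns; some of them disagree with any single
    boundary convention, so this report is the honest reconciliation:
    recomputed values, printed values, and their deltas.
    """
    import importlib.resources

    printed = pd.read_csv(importlib.resources.files("budcast") / "data" / "amf_apis.csv")
    printed = printed.set_index("name")
    rows = []
    for name, api in ds.apis.items():
        mc, msc = molecule_class(api), molecular_structure_class(api)
        mc_p = int(printed.loc[name, "mc_printed"]) if name in printed.index else None
        msc_p = int(printed.loc[name, "msc_printed"]) if name in printed.index else None
        rows.append(
            {
                "api": name,
                "mc_computed": mc, "mc_printed": mc_p,
                "mc_delta": None if mc_p is None else mc - mc_p,
                "msc_computed": msc, "msc_printed": msc_p,
                "msc_delta": None if msc_p is None else msc - msc_p,
            }
        )
    return pd.DataFrame(rows)
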