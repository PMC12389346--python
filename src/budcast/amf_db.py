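"""Data model and CSV I/O for the curated formulation-stability database (AMF-DB).

The database has three tables: API molecular descriptors, excipient
descriptors/properties, and experimental stability records of compounded
oral solid preparations with their beyond-use dates (BUD, days).  This
module validates the tables, resolves cross-references, and preserves row
order so that the linear train/test partition downstream is reproducible.

Sentinel conventions in the CSV files: ``ND`` marks an undocumented
categorical value (packaging, excipient), ``-`` a missing numeric value or
absent excipient.  Both are represented as ``None`` in memory — never as 0.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "EXCIPIENT_NAMES",
    "PACKAGING_TYPES",
    "APIDescriptorRecord",
    "ExcipientRecord",
    "StabilityRecord",
    "CuratedDataset",
    "SchemaError",
    "ReferentialError",
    "ParseError",
    "load_dataset",
    "load_packaged_dataset",
    "save_dataset",
    "dataset_summary",
]

#: Canonical excipient vocabulary (closed set; lowercase ASCII).
EXCIPIENT_NAMES = ("lactose", "silica", "cellulose", "mannitol", "sucrose", "hpmc")

#: Known packaging materials; ``None`` encodes "not documented".
PACKAGING_TYPES = ("glass", "plastic", "paper")

_SENTINELS = {"ND", "-", "", "NA"}

_PACKAGING_ALIASES = {
    "g": "glass",
    "glass": "glass",
    "pl": "plastic",
    "plastic": "plastic",
    "p": "paper",
    "paper": "paper",
}

_STABILITY_COLUMNS = [
    "api_name",
    "main_excipient",
    "other_excipient",
    "packaging",
    "dose_mg",
    "content_pct",
    "temperature_c",
    "bud_days",
]
_API_COLUMNS = ["name", "smiles", "mw", "logp", "rb", "ps", "hbd", "hba", "ar"]
_EXCIPIENT_COLUMNS = _API_COLUMNS + ["functional_roles", "solid_form", "shelf_life_years"]


class SchemaError(ValueError):
    """A required column is missing or a header does not match the schema."""


class ReferentialError(ValueError):
    """A stability record references an API or excipient that does not exist."""


class ParseError(ValueError):
    """A cell could not be parsed as the declared type."""


@dataclass(frozen=True)
class APIDescriptorRecord:
    """Molecular descriptors of one active pharmaceutical ingredient.

    ``smiles`` is an opaque identifier: it is label-encoded downstream,
    never parsed.  Descriptor symbols follow cheminformatics convention:
    MW (g/mol), LogP, rotatable bonds, polar surface area (Å²), H-bond
    donors/acceptors, aromatic rings.
    """

    name: str
    smiles: str
    mw: float
    logp: float
    rb: int
    ps: float
    hbd: int
    hba: int
    ar: int

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise ParseError(f"API {self.name!r}: mw must be > 0, got {self.mw}")
        if self.ps < 0:
            raise ParseError(f"API {self.name!r}: ps must be >= 0, got {self.ps}")
        for attr in ("rb", "hbd", "hba", "ar"):
            v = getattr(self, attr)
            if not (isinstance(v, (int,)) and v >= 0):
                raise ParseError(f"API {self.name!r}: {attr} must be a non-negative integer, got {v!r}")


@dataclass(frozen=True)
class ExcipientRecord:
    """One of the six supported excipients with descriptors and properties."""

    name: str
    display_name: str
    descriptors: APIDescriptorRecord
    functional_roles: frozenset[str]
    shelf_life_years: float
    solid_form: str

    def __post_init__(self) -> None:
        if self.name not in EXCIPIENT_NAMES:
            raise ParseError(f"unknown excipient name {self.name!r}; expected one of {EXCIPIENT_NAMES}")
        if not self.shelf_life_years > 0:
            raise ParseError(f"excipient {self.name!r}: shelf_life_years must be > 0")
        if self.solid_form not in ("crystalline", "amorphous", "mixed"):
            raise ParseError(f"excipient {self.name!r}: invalid solid_form {self.solid_form!r}")


@dataclass(frozen=True)
class StabilityRecord:
    """One experimental formulation/storage observation.

    ``main_excipient is None`` means the excipient is undocumented or the
    preparation is pure API; ``other_excipient is None`` means no second
    excipient; ``packaging is None`` means packaging was not documented;
    ``dose_mg``/``content_pct`` are ``None`` when missing.
    """

    api_name: str
    main_excipient: str | None
    other_excipient: str | None
    packaging: str | None
    dose_mg: float | None
    content_pct: float | None
    temperature_c: float
    bud_days: float

    def __post_init__(self) -> None:
        if not self.bud_days > 0:
            raise ParseError(f"record for {self.api_name!r}: bud_days must be > 0, got {self.bud_days}")
        if self.content_pct is not None and not (0 < self.content_pct <= 100):
            raise ParseError(
                f"record for {self.api_name!r}: content_pct must be in (0, 100], got {self.content_pct}"
            )
        if self.packaging is not None and self.packaging not in PACKAGING_TYPES:
            raise ParseError(f"record for {self.api_name!r}: invalid packaging {self.packaging!r}")
        if self.main_excipient is not None and self.main_excipient == self.other_excipient:
            raise ParseError(f"record for {self.api_name!r}: duplicated excipient {self.main_excipient!r}")

    @property
    def excipients(self) -> frozenset[str]:
        """Set of excipients present (0–2 names)."""
        return frozenset(e for e in (self.main_excipient, self.other_excipient) if e is not None)


@dataclass
class CuratedDataset:
    """The three validated tables; stability records keep file order."""

    apis: dict[str, APIDescriptorRecord]
    excipients: dict[str, ExcipientRecord]
    records: list[StabilityRecord]

    def api_for(self, record: StabilityRecord) -> APIDescriptorRecord:
        return self.apis[record.api_name]

    def validate_references(self) -> None:
        """Check every record resolves its API and excipient names."""
        for i, rec in enumerate(self.records):
            if rec.api_name not in self.apis:
                raise ReferentialError(f"row {i}: unknown api_name {rec.api_name!r}")
            for exc in rec.excipients:
                if exc not in self.excipients:
                    raise ReferentialError(f"row {i}: unknown excipient {exc!r}")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _clean(value: object) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return None if s in _SENTINELS else s


def _parse_float(value: object, *, row: int, column: str, path: str | Path) -> float | None:
    s = _clean(value)
    if s is None:
        return None
    try:
        return float(s)
    except ValueError:
        raise ParseError(f"{path}, row {row}, column {column!r}: not numeric: {s!r}") from None


def _parse_int(value: object, *, row: int, column: str, path: str | Path) -> int | None:
    f = _parse_float(value, row=row, column=column, path=path)
    if f is None:
        return None
    if f != int(f):
        raise ParseError(f"{path}, row {row}, column {column!r}: expected integer, got {f}")
    return int(f)


def _canonical_excipient(name: str | None, *, row: int, path: str | Path) -> str | None:
    if name is None:
        return None
    canon = name.strip().lower()
    if canon not in EXCIPIENT_NAMES:
        raise ReferentialError(f"{path}, row {row}: unknown excipient {name!r}")
    return canon


def _canonical_packaging(token: str | None, *, row: int, path: str | Path) -> str | None:
    if token is None:
        return None
    canon = _PACKAGING_ALIASES.get(token.strip().lower())
    if canon is None:
        raise ParseError(f"{path}, row {row}: unknown packaging {token!r}")
    return canon


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty (header row required)") from None


def load_api_table(path: str | Path) -> dict[str, APIDescriptorRecord]:
    df = _read_csv(path)
    _require_columns(df, _API_COLUMNS, path)
    apis: dict[str, APIDescriptorRecord] = {}
    for i, row in df.iterrows():
        name = _clean(row["name"])
        if name is None:
            raise ParseError(f"{path}, row {i}: empty API name")
        apis[name] = APIDescriptorRecord(
            name=name,
            smiles=_clean(row["smiles"]) or "",
            mw=_parse_float(row["mw"], row=i, column="mw", path=path),
            logp=_parse_float(row["logp"], row=i, column="logp", path=path),
            rb=_parse_int(row["rb"], row=i, column="rb", path=path),
            ps=_parse_float(row["ps"], row=i, column="ps", path=path),
            hbd=_parse_int(row["hbd"], row=i, column="hbd", path=path),
            hba=_parse_int(row["hba"], row=i, column="hba", path=path),
            ar=_parse_int(row["ar"], row=i, column="ar", path=path),
        )
    return apis


def load_excipient_table(path: str | Path) -> dict[str, ExcipientRecord]:
    df = _read_csv(path)
    _require_columns(df, _EXCIPIENT_COLUMNS, path)
    excipients: dict[str, ExcipientRecord] = {}
    for i, row in df.iterrows():
        raw_name = _clean(row["name"])
        if raw_name is None:
            raise ParseError(f"{path}, row {i}: empty excipient name")
        name = raw_name.lower()
        display = _clean(row["display_name"]) if "display_name" in df.columns else None
        descriptors = APIDescriptorRecord(
            name=name,
            smiles=_clean(row["smiles"]) or "",
            mw=_parse_float(row["mw"], row=i, column="mw", path=path),
            logp=_parse_float(row["logp"], row=i, column="logp", path=path),
            rb=_parse_int(row["rb"], row=i, column="rb", path=path),
            ps=_parse_float(row["ps"], row=i, column="ps", path=path),
            hbd=_parse_int(row["hbd"], row=i, column="hbd", path=path),
            hba=_parse_int(row["hba"], row=i, column="hba", path=path),
            ar=_parse_int(row["ar"], row=i, column="ar", path=path),
        )
        roles = _clean(row["functional_roles"]) or ""
        excipients[name] = ExcipientRecord(
            name=name,
            display_name=display or raw_name,
            descriptors=descriptors,
            functional_roles=frozenset(r.strip() for r in roles.split(";") if r.strip()),
            shelf_life_years=_parse_float(row["shelf_life_years"], row=i, column="shelf_life_years", path=path),
            solid_form=_clean(row["solid_form"]) or "",
        )
    return excipients


def load_stability_table(path: str | Path) -> list[StabilityRecord]:
    df = _read_csv(path)
    _require_columns(df, _STABILITY_COLUMNS, path)
    records: list[StabilityRecord] = []
    for i, row in df.iterrows():
        api_name = _clean(row["api_name"])
        if api_name is None:
            raise ParseError(f"{path}, row {i}: empty api_name")
        temperature = _parse_float(row["temperature_c"], row=i, column="temperature_c", path=path)
        bud = _parse_float(row["bud_days"], row=i, column="bud_days", path=path)
        if temperature is None or bud is None:
            raise ParseError(f"{path}, row {i}: temperature_c and bud_days are required")
        records.append(
            StabilityRecord(
                api_name=api_name,
                main_excipient=_canonical_excipient(_clean(row["main_excipient"]), row=i, path=path),
                other_excipient=_canonical_excipient(_clean(row["other_excipient"]), row=i, path=path),
                packaging=_canonical_packaging(_clean(row["packaging"]), row=i, path=path),
                dose_mg=_parse_float(row["dose_mg"], row=i, column="dose_mg", path=path),
                content_pct=_parse_float(row["content_pct"], row=i, column="content_pct", path=path),
                temperature_c=temperature,
                bud_days=bud,
            )
        )
    return records


def load_dataset(
    stability_path: str | Path, api_path: str | Path, excipient_path: str | Path
) -> CuratedDataset:
    """Load and validate the three CSV tables into a :class:`CuratedDataset`.

    Row order of the stability table is preserved (it defines the linear
    train/test partition).  Raises :class:`SchemaError`,
    :class:`ReferentialError` or :class:`ParseError` with the offending
    row/column named.
    """
    ds = CuratedDataset(
        apis=load_api_table(api_path),
        excipients=load_excipient_table(excipient_path),
        records=load_stability_table(stability_path),
    )
    ds.validate_references()
    return ds


def _data_dir() -> Path:
    return Path(importlib.resources.files("budcast") / "data")


def load_packaged_dataset() -> CuratedDataset:
    """Load the packaged 53-record curated stability dataset (22 APIs, 6 excipients)."""
    d = _data_dir()
    return load_dataset(d / "amf_stability.csv", d / "amf_apis.csv", d / "amf_excipients.csv")


def save_dataset(
    ds: CuratedDataset,
    stability_path: str | Path,
    api_path: str | Path,
    excipient_path: str | Path,
) -> None:
    """Write the dataset back to the three-CSV layout (round-trip safe)."""

    def fmt(v: object) -> str:
        if v is None:
            return "-"
        if isinstance(v, float) and v == int(v):
            return str(int(v))
        return str(v)

    api_rows = [
        {
            "name": a.name, "smiles": a.smiles, "mw": a.mw, "logp": a.logp, "rb": a.rb,
            "ps": a.ps, "hbd": a.hbd, "hba": a.hba, "ar": a.ar,
        }
        for a in ds.apis.values()
    ]
    pd.DataFrame(api_rows, columns=_API_COLUMNS).to_csv(api_path, index=False)

    exc_rows = [
        {
            "name": e.name, "display_name": e.display_name, "smiles": e.descriptors.smiles,
            "mw": e.descriptors.mw, "logp": e.descriptors.logp, "rb": e.descriptors.rb,
            "ps": e.descriptors.ps, "hbd": e.descriptors.hbd, "hba": e.descriptors.hba,
            "ar": e.descriptors.ar,
            "functional_roles": ";".join(sorted(e.functional_roles)),
            "solid_form": e.solid_form, "shelf_life_years": e.shelf_life_years,
        }
        for e in ds.excipients.values()
    ]
    pd.DataFrame(exc_rows, columns=["name", "display_name"] + _EXCIPIENT_COLUMNS[1:]).to_csv(
        excipient_path, index=False
    )

    _PACK_OUT = {"glass": "G", "plastic": "Pl", "paper": "P", None: "ND"}
    stab_rows = [
        {
            "api_name": r.api_name,
            "main_excipient": r.main_excipient if r.main_excipient is not None else "-",
            "other_excipient": r.other_excipient if r.other_excipient is not None else "-",
            "packaging": _PACK_OUT[r.packaging],
            "dose_mg": fmt(r.dose_mg),
            "content_pct": fmt(r.content_pct),
            "temperature_c": fmt(r.temperature_c),
            "bud_days": fmt(r.bud_days),
        }
        for r in ds.records
    ]
    pd.DataFrame(stab_rows, columns=_STABILITY_COLUMNS).to_csv(stability_path, index=False)


def dataset_summary(ds: CuratedDataset) -> dict:
    """Exact-enumeration summary: counts and [min, max] ranges over non-missing values."""

    def rng(values: list[float]) -> tuple[float, float] | None:
        return (min(values), max(values)) if values else None

    temps = [r.temperature_c for r in ds.records]
    contents = [r.content_pct for r in ds.records if r.content_pct is not None]
    buds = [r.bud_days for r in ds.records]
    packagings = sorted({r.packaging for r in ds.records if r.packaging is not None})
    return {
        "n_records": len(ds.records),
        "n_apis": len({r.api_name for r in ds.records}),
        "n_excipients": len(ds.excipients),
        "packaging_types": packagings,
        "n_packaging_types": len(packagings),
        "temperature_range_c": rng(temps),
        "content_range_pct": rng(contents),
        "bud_range_days": rng(buds),
    }
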