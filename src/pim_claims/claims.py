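"""Claims tables: domain types, CSV readers/writers and invariant validation.

A study dataset is a :class:`ClaimsBundle` of five linked tables —
persons, enrollment spans, medical claims, pharmacy fills and a drug
dictionary — held as pandas DataFrames with a fixed column schema.
Validation is strict-fail: a dangling foreign key or an invariant breach
raises :class:`BundleValidationError` naming the offending rows rather
than silently dropping records.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

SEXES = ("female", "male")
REGIONS = ("northeast", "midwest", "south", "west")
INSURANCE_TYPES = ("hmo", "other")
SETTINGS = ("inpatient", "outpatient", "other")
SERVICE_TYPES = ("visit", "physical_therapy", "ia_corticosteroid", "ia_hyaluronic_acid", "other")
DRUG_CLASSES = (
    "nsaid_nonselective",
    "nsaid_selective",
    "corticosteroid",
    "antiplatelet",
    "ssri",
    "aspirin",
    "anticoagulant",
    "opioid",
    "other",
)
NSAID_CLASSES = ("nsaid_nonselective", "nsaid_selective")

COLUMNS: Mapping[str, tuple[str, ...]] = {
    "persons": ("person_id", "birth_year", "sex", "region", "insurance_type"),
    "enrollment": ("person_id", "start_date", "end_date", "medical", "pharmacy"),
    "medical_claims": (
        "person_id",
        "service_date",
        "setting",
        "provider_id",
        "diagnosis_codes",
        "service_type",
    ),
    "fills": ("person_id", "drug_code", "fill_date", "days_supply", "quantity", "unit_strength_mg"),
    "drug_dictionary": ("drug_code", "ingredient", "drug_class"),
}

_ICD_RE = re.compile(r"^[A-Z][A-Z0-9]{2,6}$")


class BundleValidationError(ValueError):
    """Raised when a bundle violates its schema or referential integrity.

    ``rows`` holds the offending (table, index) pairs for diagnostics.
    """

    def __init__(self, message: str, rows: list[tuple[str, int]] | None = None):
        super().__init__(message)
        self.rows = rows or []


@dataclass
class ClaimsBundle:
    """The five linked claims tables constituting one study dataset."""

    persons: pd.DataFrame
    enrollment: pd.DataFrame
    medical_claims: pd.DataFrame
    fills: pd.DataFrame
    drug_dictionary: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "persons": self.persons,
            "enrollment": self.enrollment,
            "medical_claims": self.medical_claims,
            "fills": self.fills,
            "drug_dictionary": self.drug_dictionary,
        }


def normalize_icd(code: str) -> str:
    """Uppercase, dotless ICD-10 form, e.g. ``m17.11 -> M1711``."""
    return code.strip().upper().replace(".", "")


def _fail(table: str, idx: list[int], message: str) -> None:
    shown = idx[:20]
    raise BundleValidationError(
        f"{table}: {message} (rows {shown}{'...' if len(idx) > 20 else ''})",
        rows=[(table, i) for i in idx],
    )


def _check_enum(df: pd.DataFrame, table: str, col: str, allowed: tuple[str, ...]) -> None:
    bad = df.index[~df[col].isin(allowed)].tolist()
    if bad:
        _fail(table, bad, f"column {col!r} outside {allowed}")


def _parse_dates(df: pd.DataFrame, table: str, col: str) -> None:
    parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    bad = df.index[parsed.isna()].tolist()
    if bad:
        _fail(table, bad, f"column {col!r} not an ISO-8601 date")
    df[col] = parsed.dt.date


def _parse_bool(df: pd.DataFrame, table: str, col: str) -> None:
    mapping = {"true": True, "false": False, "True": True, "False": False,
               "1": True, "0": False, True: True, False: False}
    vals = df[col].map(mapping)
    bad = df.index[vals.isna()].tolist()
    if bad:
        _fail(table, bad, f"column {col!r} not a boolean")
    df[col] = vals.astype(bool)


def validate_bundle(bundle: ClaimsBundle) -> ClaimsBundle:
    """Validate all schema and referential-integrity invariants in place."""
    for name, df in bundle.tables().items():
        missing = [c for c in COLUMNS[name] if c not in df.columns]
        if missing:
            raise BundleValidationError(f"{name}: missing columns {missing}")

    p = bundle.persons
    dup = p.index[p["person_id"].duplicated()].tolist()
    if dup:
        _fail("persons", dup, "duplicate person_id")
    p["birth_year"] = p["birth_year"].astype(int)
    bad = p.index[(p["birth_year"] < 1900) | (p["birth_year"] > 2000)].tolist()
    if bad:
        _fail("persons", bad, "implausible birth_year (expect 1900-2000)")
    _check_enum(p, "persons", "sex", SEXES)
    _check_enum(p, "persons", "region", REGIONS)
    _check_enum(p, "persons", "insurance_type", INSURANCE_TYPES)

    e = bundle.enrollment
    for col in ("start_date", "end_date"):
        if not e.empty and not isinstance(e[col].iloc[0], datetime.date):
            _parse_dates(e, "enrollment", col)
    for col in ("medical", "pharmacy"):
        if not e.empty and e[col].dtype != bool:
            _parse_bool(e, "enrollment", col)
    if not e.empty:
        bad = e.index[e["start_date"] > e["end_date"]].tolist()
        if bad:
            _fail("enrollment", bad, "start_date after end_date")

    m = bundle.medical_claims
    if not m.empty and not isinstance(m["service_date"].iloc[0], datetime.date):
        _parse_dates(m, "medical_claims", "service_date")
    _check_enum(m, "medical_claims", "setting", SETTINGS)
    _check_enum(m, "medical_claims", "service_type", SERVICE_TYPES)
    if not m.empty:
        if m["diagnosis_codes"].dtype == object and isinstance(m["diagnosis_codes"].iloc[0], str):
            m["diagnosis_codes"] = [
                [normalize_icd(c) for c in s.split(";") if c.strip()] if s else []
                for s in m["diagnosis_codes"].fillna("")
            ]
        bad = [
            i
            for i, codes in zip(m.index, m["diagnosis_codes"])
            if any(not _ICD_RE.match(c) for c in codes)
        ]
        if bad:
            _fail("medical_claims", bad, "malformed ICD-10 code (expect dotless uppercase)")

    f = bundle.fills
    if not f.empty and not isinstance(f["fill_date"].iloc[0], datetime.date):
        _parse_dates(f, "fills", "fill_date")
    if not f.empty:
        f["days_supply"] = f["days_supply"].astype(int)
        f["quantity"] = f["quantity"].astype(float)
        f["unit_strength_mg"] = f["unit_strength_mg"].astype(float)
        bad = f.index[f["days_supply"] < 1].tolist()
        if bad:
            _fail("fills", bad, "days_supply < 1")
        bad = f.index[f["quantity"] <= 0].tolist()
        if bad:
            _fail("fills", bad, "quantity <= 0")
        bad = f.index[f["unit_strength_mg"] < 0].tolist()
        if bad:
            _fail("fills", bad, "unit_strength_mg < 0")

    d = bundle.drug_dictionary
    dup = d.index[d["drug_code"].duplicated()].tolist()
    if dup:
        _fail("drug_dictionary", dup, "duplicate drug_code")
    _check_enum(d, "drug_dictionary", "drug_class", DRUG_CLASSES)

    known_persons = set(p["person_id"])
    for name in ("enrollment", "medical_claims", "fills"):
        df = bundle.tables()[name]
        if df.empty:
            continue
        bad = df.index[~df["person_id"].isin(known_persons)].tolist()
        if bad:
            _fail(name, bad, "person_id not in persons (dangling foreign key)")
    if not f.empty:
        known_codes = set(d["drug_code"])
        bad = f.index[~f["drug_code"].isin(known_codes)].tolist()
        if bad:
            _fail("fills", bad, "drug_code not in drug_dictionary (dangling foreign key)")
    return bundle


def read_bundle(paths: Mapping[str, Path | str]) -> ClaimsBundle:
    """Read the five CSV tables and return a validated bundle.

    ``paths`` maps table name (persons, enrollment, medical_claims, fills,
    drug_dictionary) to a CSV file path.
    """
    frames = {}
    for name in COLUMNS:
        if name not in paths:
            raise BundleValidationError(f"missing path for table {name!r}")
        frames[name] = pd.read_csv(paths[name], dtype={"person_id": str, "drug_code": str,
                                                       "provider_id": str}, keep_default_na=False,
                                   na_values=[])
    bundle = ClaimsBundle(**frames)
    return validate_bundle(bundle)


def write_bundle(bundle: ClaimsBundle, directory: Path | str) -> dict[str, Path]:
    """Write the five tables as CSVs under ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in bundle.tables().items():
        out = df.copy()
        if name == "medical_claims" and not out.empty and not isinstance(
            out["diagnosis_codes"].iloc[0], str
        ):
            out["diagnosis_codes"] = [";".join(codes) for codes in out["diagnosis_codes"]]
        if name == "enrollment" and not out.empty:
            out["medical"] = out["medical"].map({True: "true", False: "false"})
            out["pharmacy"] = out["pharmacy"].map({True: "true", False: "false"})
        path = directory / f"{name}.csv"
        out.to_csv(path, index=False)
        paths[name] = path
    return paths


def rows_in_period(df: pd.DataFrame, date_col: str, period) -> pd.DataFrame:
    """Rows whose ``date_col`` falls inside the closed ``period``."""
    if df.empty:
        return df
    mask = pd.Series(
        [(period.start <= d <= period.end) for d in df[date_col]], index=df.index
    )
    return df[mask]


@dataclass
class DrugInfo:
    """Resolved dictionary entry for one drug code."""

    drug_code: str
    ingredient: str
    drug_class: str


def drug_lookup(dictionary: pd.DataFrame) -> dict[str, DrugInfo]:
    return {
        r.drug_code: DrugInfo(r.drug_code, r.ingredient, r.drug_class)
        for r in dictionary.itertuples()
    }
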