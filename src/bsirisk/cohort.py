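"""Cohort data model: patient records, missing-value semantics, CSV I/O.

The analysis unit is a blood-culture *event* sampled at presentation to an
emergency department. Each event carries demographics, vital signs, laboratory
values, the binary components of the Shapiro decision rule, SOFA totals and
the adjudicated blood-culture outcome. Any non-identifier field may be
missing; missingness is represented as ``None`` throughout and maps to an
empty cell in CSV.

Canonical units are fixed internally: creatinine in µmol/L, cell counts and
platelets in 10⁹/L, temperature in °C, lactate in mmol/L, CRP in mg/L,
bilirubin in µmol/L. A schema configuration may declare a source file's
creatinine column as mg/dL, in which case values are converted (×88.4) on
read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Optional

import pandas as pd
import yaml

__all__ = [
    "Pathogen",
    "PatientRecord",
    "CohortTable",
    "load_schema",
    "read_cohort_csv",
    "write_cohort_csv",
    "completeness_report",
    "CREATININE_MGDL_TO_UMOLL",
]

#: conversion factor from mg/dL to µmol/L for creatinine
CREATININE_MGDL_TO_UMOLL = 88.4

CULTURE_OUTCOMES = ("positive_relevant", "negative", "contaminant")

_TRUE_TOKENS = {"1", "true", "yes"}
_FALSE_TOKENS = {"0", "false", "no"}


@dataclass(frozen=True)
class Pathogen:
    """A bacterial isolate from a positive blood culture."""

    species: str
    gram: str  # "negative" | "positive"

    def __post_init__(self) -> None:
        if self.gram not in ("negative", "positive"):
            raise ValueError(f"gram must be 'negative' or 'positive', got {self.gram!r}")


@dataclass
class PatientRecord:
    """One blood-culture event. All non-identifier fields are optional."""

    event_id: str
    age: Optional[float] = None                 # years
    sex: Optional[str] = None                   # "male" | "female"
    temperature: Optional[float] = None         # °C
    systolic_bp: Optional[float] = None         # mmHg
    respiratory_rate: Optional[float] = None    # breaths/min
    heart_rate: Optional[float] = None          # beats/min
    wbc: Optional[float] = None                 # 10⁹/L
    neutrophils: Optional[float] = None         # 10⁹/L
    lymphocytes: Optional[float] = None         # 10⁹/L
    platelets: Optional[float] = None           # 10⁹/L
    creatinine: Optional[float] = None          # µmol/L
    lactate: Optional[float] = None             # mmol/L
    crp: Optional[float] = None                 # mg/L
    bilirubin: Optional[float] = None           # µmol/L
    chills: Optional[bool] = None
    suspected_endocarditis: Optional[bool] = None
    indwelling_vascular_catheter: Optional[bool] = None
    altered_mentation: Optional[bool] = None
    sofa_baseline: Optional[int] = None         # points, 0-24
    sofa_admission: Optional[int] = None        # points, 0-24
    culture_outcome: str = "negative"
    pathogens: list[Pathogen] = field(default_factory=list)

    @property
    def culture_positive(self) -> bool:
        """True when the culture grew a clinically relevant pathogen.

        Contaminants are grouped with negatives for all accuracy analyses.
        """
        return self.culture_outcome == "positive_relevant"

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated domain invariant."""
        if not self.event_id:
            raise ValueError("event_id must be non-empty")
        if self.age is not None and self.age < 18:
            raise ValueError(f"{self.event_id}: age {self.age} below adult inclusion (>=18)")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"{self.event_id}: sex must be 'male' or 'female'")
        if self.temperature is not None and not (25.0 <= self.temperature <= 45.0):
            raise ValueError(f"{self.event_id}: temperature {self.temperature} outside [25, 45] C")
        for name in ("systolic_bp", "respiratory_rate", "heart_rate", "wbc",
                     "neutrophils", "lymphocytes", "platelets", "creatinine",
                     "lactate", "crp", "bilirubin"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{self.event_id}: {name} = {v} must be finite and >= 0")
        for name in ("sofa_baseline", "sofa_admission"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 24):
                raise ValueError(f"{self.event_id}: {name} = {v} outside [0, 24]")
        if self.culture_outcome not in CULTURE_OUTCOMES:
            raise ValueError(f"{self.event_id}: unknown culture_outcome {self.culture_outcome!r}")
        if (self.culture_outcome == "positive_relevant") != bool(self.pathogens):
            raise ValueError(
                f"{self.event_id}: pathogens must be non-empty iff culture is positive_relevant"
            )


# CSV schema: column -> (python kind, unit label). Order fixes the file layout.
_COLUMNS: dict[str, tuple[str, str]] = {
    "event_id": ("str", ""),
    "age": ("float", "years"),
    "sex": ("category", "male|female"),
    "temperature": ("float", "C"),
    "systolic_bp": ("float", "mmHg"),
    "respiratory_rate": ("float", "breaths/min"),
    "heart_rate": ("float", "beats/min"),
    "wbc": ("float", "1e9/L"),
    "neutrophils": ("float", "1e9/L"),
    "lymphocytes": ("float", "1e9/L"),
    "platelets": ("float", "1e9/L"),
    "creatinine": ("float", "umol/L"),
    "lactate": ("float", "mmol/L"),
    "crp": ("float", "mg/L"),
    "bilirubin": ("float", "umol/L"),
    "chills": ("bool", ""),
    "suspected_endocarditis": ("bool", ""),
    "indwelling_vascular_catheter": ("bool", ""),
    "altered_mentation": ("bool", ""),
    "sofa_baseline": ("int", "points"),
    "sofa_admission": ("int", "points"),
    "culture_outcome": ("category", "positive_relevant|negative|contaminant"),
    "pathogens": ("pathogens", "species|gram;..."),
}

_OPTIONAL_FIELDS = [c for c in _COLUMNS if c not in ("event_id", "culture_outcome", "pathogens")]


def load_schema(path=None) -> dict:
    """Load the machine-readable cohort schema (column, unit, type, values).

    Without ``path`` the packaged default schema is returned.
    """
    if path is None:
        text = resources.files("bsirisk.data").joinpath("cohort_schema.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


@dataclass
class CohortTable:
    """Ordered collection of :class:`PatientRecord` with provenance metadata."""

    records: list[PatientRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.event_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate event_id values: {dupes}")
        self.metadata.setdefault("n_events", len(self.records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i) -> PatientRecord:
        return self.records[i]

    @property
    def n_positive(self) -> int:
        return sum(r.culture_positive for r in self.records)

    def validate(self) -> None:
        for r in self.records:
            r.validate()

    def to_dataframe(self) -> pd.DataFrame:
        """Render the cohort as a DataFrame in canonical column order."""
        rows = [_record_to_row(r) for r in self.records]
        return pd.DataFrame(rows, columns=list(_COLUMNS))


def _format_pathogens(pathogens: list[Pathogen]) -> str:
    return ";".join(f"{p.species}|{p.gram}" for p in pathogens)


def _parse_pathogens(cell: str, row_ix: int) -> list[Pathogen]:
    if not cell:
        return []
    out = []
    for item in cell.split(";"):
        try:
            species, gram = item.rsplit("|", 1)
            out.append(Pathogen(species=species, gram=gram))
        except ValueError as exc:
            raise ValueError(f"row {row_ix}: unparseable pathogen entry {item!r}") from exc
    return out


def _record_to_row(r: PatientRecord) -> dict:
    row: dict = {}
    for col, (kind, _) in _COLUMNS.items():
        v = getattr(r, col) if col != "pathogens" else None
        if col == "pathogens":
            row[col] = _format_pathogens(r.pathogens)
        elif v is None:
            row[col] = ""
        elif kind == "bool":
            row[col] = "1" if v else "0"
        elif kind == "int":
            row[col] = str(int(v))
        elif kind == "float":
            row[col] = repr(float(v))
        else:
            row[col] = str(v)
    return row


def _parse_cell(col: str, kind: str, cell: str, row_ix: int):
    if cell == "":
        return None
    if kind == "float":
        try:
            return float(cell)
        except ValueError as exc:
            raise ValueError(f"row {row_ix}, column {col!r}: unparseable numeric {cell!r}") from exc
    if kind == "int":
        try:
            return int(float(cell))
        except ValueError as exc:
            raise ValueError(f"row {row_ix}, column {col!r}: unparseable integer {cell!r}") from exc
    if kind == "bool":
        token = cell.strip().lower()
        if token in _TRUE_TOKENS:
            return True
        if token in _FALSE_TOKENS:
            return False
        raise ValueError(f"row {row_ix}, column {col!r}: unparseable boolean {cell!r}")
    return cell


def read_cohort_csv(path, schema_config: dict | None = None) -> CohortTable:
    """Read a cohort CSV into a :class:`CohortTable`.

    Parameters
    ----------
    path
        CSV file (comma-separated, UTF-8, ``.`` decimal separator, header
        required) whose columns are exactly the canonical schema.
    schema_config
        Optional dict; ``schema_config["units"]["creatinine"] == "mg/dL"``
        declares the creatinine column in mg/dL, converted to µmol/L on read.

    Empty cells become missing (``None``). Booleans accept 0/1/true/false/
    yes/no case-insensitively. Unknown columns, unparseable values and
    duplicate event ids are hard errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in _COLUMNS]
    if unknown:
        raise ValueError(f"unknown columns in {path}: {unknown}")
    absent = [c for c in _COLUMNS if c not in df.columns]
    if absent:
        raise ValueError(f"missing required columns in {path}: {absent}")

    units = (schema_config or {}).get("units", {})
    creat_unit = units.get("creatinine", "umol/L")
    if creat_unit not in ("umol/L", "mg/dL"):
        raise ValueError(f"unsupported creatinine unit {creat_unit!r}")

    records = []
    for ix, row in enumerate(df.itertuples(index=False), start=1):
        values = dict(zip(df.columns, row))
        kwargs: dict = {}
        for col, (kind, _) in _COLUMNS.items():
            if col == "pathogens":
                kwargs[col] = _parse_pathogens(values[col], ix)
            else:
                kwargs[col] = _parse_cell(col, kind, values[col], ix)
        if kwargs["creatinine"] is not None and creat_unit == "mg/dL":
            kwargs["creatinine"] = kwargs["creatinine"] * CREATININE_MGDL_TO_UMOLL
        if kwargs["culture_outcome"] is None:
            raise ValueError(f"row {ix}: culture_outcome is required")
        records.append(PatientRecord(**kwargs))
    cohort = CohortTable(records, metadata={"source": str(path)})
    cohort.validate()
    return cohort


def write_cohort_csv(cohort: CohortTable, path) -> None:
    """Write a cohort to CSV so that :func:`read_cohort_csv` round-trips it."""
    cohort.to_dataframe().to_csv(path, index=False)


def completeness_report(cohort: CohortTable) -> pd.DataFrame:
    """Per-field missing counts and percentages, plus the derived NLCR row.

    The NLCR row counts records where either the neutrophil or the lymphocyte
    count is missing (the ratio is then not computable).
    """
    if len(cohort) == 0:
        raise ValueError("completeness_report requires a non-empty cohort")
    n = len(cohort)
    rows = []
    for name in _OPTIONAL_FIELDS:
        n_missing = sum(getattr(r, name) is None for r in cohort)
        rows.append({"field": name, "n_missing": n_missing,
                     "pct_missing": 100.0 * n_missing / n})
    n_nlcr = sum(r.neutrophils is None or r.lymphocytes is None for r in cohort)
    rows.append({"field": "nlcr", "n_missing": n_nlcr, "pct_missing": 100.0 * n_nlcr / n})
    return pd.DataFrame(rows)
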