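"""Common data model (CDM) for a harmonized hospital EHR extract.

A :class:`CDMDataset` is a fixed set of typed pandas tables — patients, care
trajectories, ICD-10 diagnoses, ATC prescriptions, LOINC laboratory results,
admissions, imaging reports, stem-cell transplants, and a registry extract —
that every downstream engine (inclusion, regimens, toxicity, lab comparison)
consumes.  Serialization is delimited text: UTF-8 CSV (canonical) or
JSON-lines (alternate), with ISO-8601 calendar dates; only laboratory results
and imaging reports carry full timestamps.

Identifiers are opaque strings and birth is recorded as a year only — the
model deliberately carries no direct identifiers.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "CDMDataset",
    "CDMError",
    "ParseError",
    "Issue",
    "load_dataset",
    "validate_dataset",
    "write_dataset",
    "datasets_equal",
    "TABLE_SCHEMAS",
    "ICD10_RE",
    "ATC_RE",
]


class CDMError(Exception):
    """Base class for CDM I/O and validation errors."""


class ParseError(CDMError):
    """A row could not be parsed into the CDM schema."""

    def __init__(self, table: str, row: int | None, message: str):
        self.table = table
        self.row = row
        where = f"{table}.csv" if row is None else f"{table} row {row}"
        super().__init__(f"{where}: {message}")


# Column kinds drive both parsing and serialization.
#   str / str_opt      opaque or free text (opt: may be empty)
#   int                integer (year)
#   float_opt          nonnegative number or missing
#   date / date_opt    pure calendar date, ISO-8601, timezone-free
#   datetime           timestamp (labs, reports only)
#   bool               "true"/"false"
#   strlist            semicolon-joined values within one CSV cell
TABLE_SCHEMAS: dict[str, dict[str, str]] = {
    "patients": {
        "patient_id": "str",
        "birth_year": "int",
        "sex": "str",
        "resident_nl": "bool",
    },
    "trajectories": {
        "trajectory_id": "str",
        "patient_id": "str",
        "hospital_id": "str",
        "start_date": "date",
        "tumor_group": "str",
    },
    "diagnoses": {
        "patient_id": "str",
        "icd10_code": "str",
        "date": "date",
        "status": "str",
        "tumor_group": "str",
    },
    "prescriptions": {
        "patient_id": "str",
        "atc_code": "str",
        "drug_name": "str",
        "dose_mg_per_day": "float_opt",
        "start_date": "date",
        "end_date": "date_opt",
    },
    "labs": {
        "patient_id": "str",
        "loinc_code": "str",
        "analyte_name": "str",
        "value": "float",
        "unit": "str",
        "datetime": "datetime",
    },
    "admissions": {
        "patient_id": "str",
        "admit_date": "date",
        "discharge_date": "date_opt",
        "main_icd10": "str",
        "secondary_icd10": "strlist",
        "icu": "bool",
    },
    "reports": {
        "patient_id": "str",
        "datetime": "datetime",
        "modality": "str",
        "text": "str",
    },
    "sct": {
        "patient_id": "str",
        "date": "date",
        "kind": "str",
    },
    "registry": {
        "patient_id": "str",
        "tumor_group": "str",
        "diagnosis_year": "int",
        "hospital_id": "str",
    },
}

SEXES = {"female", "male", "unknown"}
TUMOR_GROUPS = {"AML", "MM", "lung", "breast"}
DIAGNOSIS_TUMOR_GROUPS = TUMOR_GROUPS | {"other"}
DIAGNOSIS_STATUSES = {"preliminary", "confirmed"}
SCT_KINDS = {"auto", "allo"}

ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.\w+)?$")
# ATC: anatomical level (1 letter + 2 digits), optionally therapeutic /
# chemical subgroup letters, optionally the 2-digit substance code.
ATC_RE = re.compile(r"^[A-Z]\d{2}([A-Z]{1,2}(\d{2})?)?$")


def _empty_table(name: str) -> pd.DataFrame:
    cols = {}
    for col, kind in TABLE_SCHEMAS[name].items():
        if kind in ("date", "date_opt", "datetime"):
            cols[col] = pd.Series(dtype="datetime64[ns]")
        elif kind == "int":
            cols[col] = pd.Series(dtype="int64")
        elif kind in ("float", "float_opt"):
            cols[col] = pd.Series(dtype="float64")
        elif kind == "bool":
            cols[col] = pd.Series(dtype="bool")
        else:
            cols[col] = pd.Series(dtype="object")
    return pd.DataFrame(cols)


@dataclass
class CDMDataset:
    """One harmonized multi-hospital EHR extract as typed pandas tables."""

    patients: pd.DataFrame = field(default_factory=lambda: _empty_table("patients"))
    trajectories: pd.DataFrame = field(default_factory=lambda: _empty_table("trajectories"))
    diagnoses: pd.DataFrame = field(default_factory=lambda: _empty_table("diagnoses"))
    prescriptions: pd.DataFrame = field(default_factory=lambda: _empty_table("prescriptions"))
    labs: pd.DataFrame = field(default_factory=lambda: _empty_table("labs"))
    admissions: pd.DataFrame = field(default_factory=lambda: _empty_table("admissions"))
    reports: pd.DataFrame = field(default_factory=lambda: _empty_table("reports"))
    sct: pd.DataFrame = field(default_factory=lambda: _empty_table("sct"))
    registry: pd.DataFrame = field(default_factory=lambda: _empty_table("registry"))
    provenance: dict = field(default_factory=dict)

    def table_names(self) -> tuple[str, ...]:
        return tuple(TABLE_SCHEMAS)

    def tables(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for name in TABLE_SCHEMAS:
            yield name, getattr(self, name)


@dataclass(frozen=True)
class Issue:
    """One invariant violation found by :func:`validate_dataset`."""

    severity: str  # "error" or "warning"
    table: str
    row: int | None
    message: str


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_cell(raw: str, kind: str):
    raw = raw.strip() if isinstance(raw, str) else raw
    if kind in ("str", "str_opt"):
        return raw
    if kind == "strlist":
        if not raw:
            return []
        return [part.strip() for part in raw.split(";") if part.strip()]
    if raw == "":
        if kind in ("date_opt", "float_opt"):
            return pd.NaT if kind == "date_opt" else math.nan
        raise ValueError("missing required value")
    if kind == "int":
        return int(raw)
    if kind in ("float", "float_opt"):
        value = float(raw)
        return value
    if kind in ("date", "date_opt"):
        ts = pd.Timestamp(raw)
        if ts.tzinfo is not None:
            raise ValueError("dates must be timezone-free")
        if ts != ts.normalize():
            raise ValueError(f"{raw!r} is not a pure calendar date")
        return ts
    if kind == "datetime":
        ts = pd.Timestamp(raw)
        if ts.tzinfo is not None:
            raise ValueError("timestamps must be timezone-free")
        return ts
    if kind == "bool":
        low = raw.lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise ValueError(f"{raw!r} is not a boolean")
    raise AssertionError(f"unknown column kind {kind}")


def _frame_from_records(name: str, records: list[dict], origin: str) -> pd.DataFrame:
    schema = TABLE_SCHEMAS[name]
    parsed: dict[str, list] = {col: [] for col in schema}
    for i, rec in enumerate(records):
        missing = [c for c in schema if c not in rec]
        if missing:
            raise ParseError(name, i + 1, f"missing column(s) {missing} in {origin}")
        for col, kind in schema.items():
            raw = rec[col]
            if raw is None:
                raw = ""
            try:
                parsed[col].append(_parse_cell(str(raw), kind))
            except (ValueError, TypeError) as exc:
                raise ParseError(name, i + 1, f"column {col!r}: {exc}") from exc
    frame = _empty_table(name)
    if records:
        frame = pd.DataFrame({col: pd.Series(vals) for col, vals in parsed.items()})
        for col, kind in schema.items():
            if kind in ("date", "date_opt", "datetime"):
                frame[col] = pd.to_datetime(frame[col])
            elif kind in ("float", "float_opt"):
                frame[col] = frame[col].astype("float64")
    _check_load_invariants(name, frame)
    return frame


def _check_load_invariants(name: str, frame: pd.DataFrame) -> None:
    """Hard row-level invariants rejected at load time (not mere warnings)."""
    if name == "prescriptions" and len(frame):
        bad = frame.index[
            frame["end_date"].notna() & (frame["end_date"] < frame["start_date"])
        ]
        if len(bad):
            row = int(bad[0]) + 1
            raise ParseError(name, row, "end_date precedes start_date")
    if name == "admissions" and len(frame):
        bad = frame.index[
            frame["discharge_date"].notna()
            & (frame["discharge_date"] < frame["admit_date"])
        ]
        if len(bad):
            row = int(bad[0]) + 1
            raise ParseError(name, row, "discharge_date precedes admit_date")


def load_dataset(path: str | Path) -> CDMDataset:
    """Read a CDM dataset from a directory of table files.

    For each table, ``<name>.csv`` is read if present, else ``<name>.jsonl``;
    a missing table yields an empty, correctly-typed frame.  Dates are parsed
    to ISO calendar dates; malformed rows raise :class:`ParseError` with the
    offending row number.
    """
    path = Path(path)
    if not path.is_dir():
        raise CDMError(f"not a dataset directory: {path}")
    ds = CDMDataset()
    for name in TABLE_SCHEMAS:
        csv_file = path / f"{name}.csv"
        jsonl_file = path / f"{name}.jsonl"
        if csv_file.exists():
            try:
                raw = pd.read_csv(csv_file, dtype=str, keep_default_na=False)
            except OSError as exc:
                raise CDMError(f"cannot read {csv_file}: {exc}") from exc
            except Exception as exc:
                raise ParseError(name, None, f"malformed CSV ({exc})") from exc
            records = raw.to_dict(orient="records")
            setattr(ds, name, _frame_from_records(name, records, str(csv_file)))
        elif jsonl_file.exists():
            records = []
            with open(jsonl_file, encoding="utf-8") as fh:
                for lineno, line in enumerate(fh, start=1):
                    if not line.strip():
                        continue
                    try:
                        rec = json.loads(line)
                    except json.JSONDecodeError as exc:
                        raise ParseError(name, lineno, f"invalid JSON: {exc}") from exc
                    records.append(
                        {k: ";".join(v) if isinstance(v, list) else v for k, v in rec.items()}
                    )
            setattr(ds, name, _frame_from_records(name, records, str(jsonl_file)))
    prov = path / "provenance.json"
    if prov.exists():
        ds.provenance = json.loads(prov.read_text(encoding="utf-8"))
    return ds


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _ref_issues(name: str, frame: pd.DataFrame, known_patients: set) -> list[Issue]:
    issues = []
    if "patient_id" not in frame.columns or not len(frame):
        return issues
    unknown = ~frame["patient_id"].isin(known_patients)
    for idx in frame.index[unknown]:
        issues.append(
            Issue("error", name, int(idx) + 1,
                  f"patient_id {frame.at[idx, 'patient_id']!r} not in patients table")
        )
    return issues


def validate_dataset(ds: CDMDataset) -> list[Issue]:
    """Return every invariant violation in ``ds`` without mutating it.

    An empty list means the dataset is internally consistent.  Issues are
    data, not exceptions: a dirty extract still loads, and the caller decides
    what to do with the report.
    """
    issues: list[Issue] = []
    pats = ds.patients
    known = set(pats["patient_id"]) if len(pats) else set()

    if len(pats):
        dup = pats["patient_id"].duplicated(keep=False)
        for idx in pats.index[dup]:
            issues.append(Issue("error", "patients", int(idx) + 1,
                                f"duplicate patient_id {pats.at[idx, 'patient_id']!r}"))
        for idx in pats.index[~pats["sex"].isin(SEXES)]:
            issues.append(Issue("error", "patients", int(idx) + 1,
                                f"sex {pats.at[idx, 'sex']!r} not in {sorted(SEXES)}"))

    for name in ("trajectories", "diagnoses", "prescriptions", "labs",
                 "admissions", "reports", "sct"):
        issues.extend(_ref_issues(name, getattr(ds, name), known))

    traj = ds.trajectories
    if len(traj):
        for idx in traj.index[~traj["tumor_group"].isin(TUMOR_GROUPS)]:
            issues.append(Issue("error", "trajectories", int(idx) + 1,
                                f"tumor_group {traj.at[idx, 'tumor_group']!r} unknown"))

    diag = ds.diagnoses
    if len(diag):
        bad_code = ~diag["icd10_code"].map(lambda c: bool(ICD10_RE.match(str(c))))
        for idx in diag.index[bad_code]:
            issues.append(Issue("error", "diagnoses", int(idx) + 1,
                                f"ICD-10 code {diag.at[idx, 'icd10_code']!r} malformed"))
        for idx in diag.index[~diag["status"].isin(DIAGNOSIS_STATUSES)]:
            issues.append(Issue("error", "diagnoses", int(idx) + 1,
                                f"status {diag.at[idx, 'status']!r} unknown"))
        for idx in diag.index[~diag["tumor_group"].isin(DIAGNOSIS_TUMOR_GROUPS)]:
            issues.append(Issue("error", "diagnoses", int(idx) + 1,
                                f"tumor_group {diag.at[idx, 'tumor_group']!r} unknown"))
        # adult registry scope: age >= 18 at every diagnosis date
        if len(pats):
            merged = diag.merge(pats[["patient_id", "birth_year"]], on="patient_id", how="left")
            ages = merged["date"].dt.year - merged["birth_year"]
            for pos in np.flatnonzero((ages < 18).to_numpy(dtype=bool, na_value=False)):
                issues.append(Issue("error", "diagnoses", int(diag.index[pos]) + 1,
                                    "patient younger than 18 at diagnosis date"))

    rx = ds.prescriptions
    if len(rx):
        bad_atc = ~rx["atc_code"].map(lambda c: bool(ATC_RE.match(str(c))))
        for idx in rx.index[bad_atc]:
            issues.append(Issue("error", "prescriptions", int(idx) + 1,
                                f"ATC code {rx.at[idx, 'atc_code']!r} malformed"))
        neg = rx["dose_mg_per_day"].notna() & (rx["dose_mg_per_day"] < 0)
        for idx in rx.index[neg]:
            issues.append(Issue("error", "prescriptions", int(idx) + 1, "negative dose"))
        inverted = rx["end_date"].notna() & (rx["end_date"] < rx["start_date"])
        for idx in rx.index[inverted]:
            issues.append(Issue("error", "prescriptions", int(idx) + 1,
                                "end_date precedes start_date"))

    labs = ds.labs
    if len(labs):
        for idx in labs.index[~np.isfinite(labs["value"].to_numpy(dtype="float64"))]:
            issues.append(Issue("error", "labs", int(idx) + 1, "non-finite value"))
        for idx in labs.index[labs["loinc_code"].astype(str).str.strip() == ""]:
            issues.append(Issue("error", "labs", int(idx) + 1, "empty LOINC code"))

    adm = ds.admissions
    if len(adm):
        inverted = adm["discharge_date"].notna() & (adm["discharge_date"] < adm["admit_date"])
        for idx in adm.index[inverted]:
            issues.append(Issue("error", "admissions", int(idx) + 1,
                                "discharge_date precedes admit_date"))
        bad_main = ~adm["main_icd10"].map(lambda c: bool(ICD10_RE.match(str(c))))
        for idx in adm.index[bad_main]:
            issues.append(Issue("error", "admissions", int(idx) + 1,
                                f"main ICD-10 {adm.at[idx, 'main_icd10']!r} malformed"))
        for idx in adm.index:
            for code in adm.at[idx, "secondary_icd10"]:
                if not ICD10_RE.match(code):
                    issues.append(Issue("error", "admissions", int(idx) + 1,
                                        f"secondary ICD-10 {code!r} malformed"))

    rep = ds.reports
    if len(rep):
        for idx in rep.index[rep["text"].astype(str).str.strip() == ""]:
            issues.append(Issue("error", "reports", int(idx) + 1, "empty report text"))

    sct = ds.sct
    if len(sct):
        for idx in sct.index[~sct["kind"].isin(SCT_KINDS)]:
            issues.append(Issue("error", "sct", int(idx) + 1,
                                f"kind {sct.at[idx, 'kind']!r} not in {sorted(SCT_KINDS)}"))

    reg = ds.registry
    if len(reg):
        dup = reg.duplicated(subset=["patient_id", "tumor_group", "diagnosis_year"], keep=False)
        for idx in reg.index[dup]:
            issues.append(Issue("error", "registry", int(idx) + 1,
                                "duplicate (patient_id, tumor_group, diagnosis_year)"))

    return issues


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _format_cell(value, kind: str) -> str:
    if kind in ("str", "str_opt"):
        return str(value)
    if kind == "strlist":
        return ";".join(value)
    if kind == "int":
        return str(int(value))
    if kind in ("float", "float_opt"):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return ""
        return repr(float(value))
    if kind in ("date", "date_opt"):
        if pd.isna(value):
            return ""
        return pd.Timestamp(value).strftime("%Y-%m-%d")
    if kind == "datetime":
        if pd.isna(value):
            return ""
        return pd.Timestamp(value).strftime("%Y-%m-%dT%H:%M:%S")
    if kind == "bool":
        return "true" if value else "false"
    raise AssertionError(f"unknown column kind {kind}")


def write_dataset(ds: CDMDataset, path: str | Path, fmt: str = "csv") -> list[Path]:
    """Serialize every table of ``ds`` under ``path``; returns written files.

    ``fmt`` is ``"csv"`` (canonical, RFC 4180, UTF-8) or ``"jsonl"``.
    Round-trip guarantee: ``load_dataset(write_dataset(ds)) == ds``
    field-for-field (see :func:`datasets_equal`).
    """
    if fmt not in ("csv", "jsonl"):
        raise ValueError(f"unknown format {fmt!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in ds.tables():
        schema = TABLE_SCHEMAS[name]
        out = pd.DataFrame(
            {col: [_format_cell(v, kind) for v in frame[col]] for col, kind in schema.items()}
        ) if len(frame) else pd.DataFrame(columns=list(schema))
        if fmt == "csv":
            target = path / f"{name}.csv"
            out.to_csv(target, index=False, encoding="utf-8", lineterminator="\n")
        else:
            target = path / f"{name}.jsonl"
            with open(target, "w", encoding="utf-8") as fh:
                for _, row in out.iterrows():
                    rec = {}
                    for col, kind in schema.items():
                        rec[col] = row[col].split(";") if kind == "strlist" and row[col] else (
                            [] if kind == "strlist" else row[col])
                    fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
        written.append(target)
    prov = path / "provenance.json"
    prov.write_text(json.dumps(ds.provenance, indent=2, sort_keys=True), encoding="utf-8")
    written.append(prov)
    return written


def datasets_equal(a: CDMDataset, b: CDMDataset) -> bool:
    """Field-for-field equality of all tables (NaN == NaN, list cells by value)."""
    for name in TABLE_SCHEMAS:
        fa, fb = getattr(a, name), getattr(b, name)
        if len(fa) != len(fb):
            return False
        if list(fa.columns) != list(fb.columns):
            return False
        for col, kind in TABLE_SCHEMAS[name].items():
            va, vb = fa[col].reset_index(drop=True), fb[col].reset_index(drop=True)
            if kind == "strlist":
                if any(list(x) != list(y) for x, y in zip(va, vb)):
                    return False
            elif kind in ("float", "float_opt"):
                if not np.array_equal(va.to_numpy(dtype="float64"),
                                      vb.to_numpy(dtype="float64"), equal_nan=True):
                    return False
            else:
                if not va.equals(vb):
                    return False
    return True
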