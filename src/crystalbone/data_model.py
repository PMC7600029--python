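"""Core domain types and CSV ingest for longitudinal EHR inputs.

Events are held in pandas DataFrames (one row per dated, coded event);
per-patient views are assembled into :class:`PatientRecord` objects.
Diagnosis codes are opaque namespaced tokens of the form
``"<SYSTEM>:<code>"`` (e.g. ``"ICD10:M80.08"``); ICD-9 and ICD-10 are never
cross-walked — each code system keeps its own namespace, and models treat
tokens as words.

All dates are handled at day resolution.  Within a day, events are ordered
lexicographically by token so that every sort is total and reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

#: days per year used for all age computations
DAYS_PER_YEAR = 365.25

DIAGNOSIS_COLUMNS = ["patient_id", "date", "code_system", "code"]
MEDICATION_COLUMNS = ["patient_id", "date", "drug"]
DEMOGRAPHICS_COLUMNS = ["patient_id", "birth_date", "sex"]

VALID_SEX = ("female", "male", "unknown")


class SchemaError(ValueError):
    """A required input column is missing."""


@dataclass
class IngestSummary:
    """Row accounting for one ingest pass: nothing is dropped silently."""

    rows_read: int = 0
    rows_kept: int = 0
    duplicates_dropped: int = 0
    rejected: dict[str, int] = field(default_factory=dict)
    unknown_drugs: list[str] = field(default_factory=list)

    def reject(self, reason: str, n: int = 1) -> None:
        if n:
            self.rejected[reason] = self.rejected.get(reason, 0) + int(n)


def make_token(system: str, code: str) -> str:
    return f"{system}:{code}"


def split_token(token: str) -> tuple[str, str]:
    """Split ``"SYSTEM:code"``; raises ValueError on malformed tokens."""
    system, sep, code = token.partition(":")
    if not sep or not system or not code or ":" in code:
        raise ValueError(f"malformed code token: {token!r}")
    return system, code


def is_valid_token(token) -> bool:
    if not isinstance(token, str):
        return False
    try:
        split_token(token)
    except ValueError:
        return False
    return True


def _require_columns(df: pd.DataFrame, columns: Iterable[str], path) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")


def _parse_dates(raw: pd.Series) -> pd.Series:
    # strict ISO first; fall back to general parsing for e.g. 2016/05/01
    dates = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    retry = dates.isna() & raw.notna()
    if retry.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dates.loc[retry] = pd.to_datetime(raw[retry], errors="coerce")
    return dates.dt.normalize()


def read_events(
    path,
    schema: str,
    drug_dictionary: set[str] | None = None,
) -> tuple[pd.DataFrame, IngestSummary]:
    """Read a long-format event CSV.

    Parameters
    ----------
    path:
        CSV file.  Diagnosis schema expects columns
        ``patient_id,date,code_system,code``; medication schema expects
        ``patient_id,date,drug``.
    schema:
        ``"diagnosis"`` or ``"medication"``.
    drug_dictionary:
        Optional set of known drug names.  Unknown drugs are kept but
        flagged in the summary.

    Returns
    -------
    (events, summary)
        ``events`` has columns ``patient_id,date,code`` (diagnosis) or
        ``patient_id,date,drug`` (medication), deterministically sorted by
        (patient_id, date, token) with exact duplicates removed.
        Rows with unparseable dates or malformed codes are rejected and
        counted, never silently dropped.
    """
    if schema not in ("diagnosis", "medication"):
        raise ValueError(f"unknown schema {schema!r}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    summary = IngestSummary(rows_read=len(raw))

    if schema == "diagnosis":
        _require_columns(raw, DIAGNOSIS_COLUMNS, path)
        token_col = "code"
    else:
        _require_columns(raw, MEDICATION_COLUMNS, path)
        token_col = "drug"

    df = raw.copy()
    df["date"] = _parse_dates(raw["date"].replace("", None))
    bad_date = df["date"].isna()
    summary.reject("bad_date", int(bad_date.sum()))
    df = df[~bad_date]

    if schema == "diagnosis":
        ok_sys = df["code_system"].str.len() > 0
        ok_code = df["code"].str.len() > 0
        no_colon = ~(df["code_system"].str.contains(":") | df["code"].str.contains(":"))
        good = ok_sys & ok_code & no_colon
        summary.reject("bad_code", int((~good).sum()))
        df = df[good]
        df = df.assign(code=df["code_system"] + ":" + df["code"])
    else:
        df["drug"] = df["drug"].str.strip().str.lower()
        bad = df["drug"].str.len() == 0
        summary.reject("bad_drug", int(bad.sum()))
        df = df[~bad]
        if drug_dictionary is not None:
            known = {d.lower() for d in drug_dictionary}
            unknown = sorted(set(df["drug"]) - known)
            summary.unknown_drugs = unknown

    bad_pid = df["patient_id"].str.len() == 0
    summary.reject("missing_patient_id", int(bad_pid.sum()))
    df = df[~bad_pid]

    before = len(df)
    df = df.drop_duplicates(subset=["patient_id", "date", token_col])
    summary.duplicates_dropped = before - len(df)

    df = df[["patient_id", "date", token_col]]
    df = df.sort_values(["patient_id", "date", token_col], kind="mergesort")
    df = df.reset_index(drop=True)
    summary.rows_kept = len(df)
    return df, summary


def read_demographics(path) -> tuple[pd.DataFrame, IngestSummary]:
    """Read the demographics CSV (``patient_id,birth_date,sex``).

    One row per patient is enforced (first occurrence wins, duplicates
    counted); unrecognised sex values become ``"unknown"``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    summary = IngestSummary(rows_read=len(raw))
    _require_columns(raw, DEMOGRAPHICS_COLUMNS, path)
    df = raw.copy()
    df["birth_date"] = _parse_dates(raw["birth_date"].replace("", None))
    bad = df["birth_date"].isna() | (df["patient_id"].str.len() == 0)
    summary.reject("bad_row", int(bad.sum()))
    df = df[~bad]
    df["sex"] = df["sex"].str.strip().str.lower()
    df.loc[~df["sex"].isin(VALID_SEX), "sex"] = "unknown"
    before = len(df)
    df = df.drop_duplicates(subset=["patient_id"], keep="first")
    summary.reject("duplicate_patient", before - len(df))
    df = df[DEMOGRAPHICS_COLUMNS].sort_values("patient_id", kind="mergesort")
    df = df.reset_index(drop=True)
    summary.rows_kept = len(df)
    return df, summary


@dataclass
class PatientRecord:
    """Demographics plus chronologically ordered events for one patient.

    ``diagnoses`` has columns (date, code) and ``medications`` (date, drug),
    both sorted ascending by (date, token).
    """

    patient_id: str
    birth_date: pd.Timestamp | None
    sex: str
    diagnoses: pd.DataFrame
    medications: pd.DataFrame
    demographics_missing: bool = False

    @property
    def first_dx_date(self) -> pd.Timestamp | None:
        if len(self.diagnoses) == 0:
            return None
        return self.diagnoses["date"].iloc[0]

    @property
    def last_dx_date(self) -> pd.Timestamp | None:
        if len(self.diagnoses) == 0:
            return None
        return self.diagnoses["date"].iloc[-1]

    def age_at(self, date: pd.Timestamp) -> float | None:
        """Age in years at ``date`` (365.25-day years); None if birth unknown."""
        if self.birth_date is None or pd.isna(self.birth_date):
            return None
        return (date - self.birth_date).days / DAYS_PER_YEAR


@dataclass
class AssemblySummary:
    n_patients: int = 0
    missing_demographics: list[str] = field(default_factory=list)
    demographics_without_events: int = 0
    events_before_birth: int = 0


_EMPTY_DX = pd.DataFrame({"date": pd.Series(dtype="datetime64[ns]"), "code": pd.Series(dtype=str)})
_EMPTY_MED = pd.DataFrame({"date": pd.Series(dtype="datetime64[ns]"), "drug": pd.Series(dtype=str)})


def assemble_records(
    diagnoses: pd.DataFrame,
    medications: pd.DataFrame | None,
    demographics: pd.DataFrame | None,
) -> tuple[dict[str, PatientRecord], AssemblySummary]:
    """Group ingested event tables into per-patient records.

    Every patient with at least one diagnosis event appears in the result.
    Patients with events but no demographics row are emitted with
    sex="unknown" and listed in the summary; demographics-only patients are
    counted but excluded.  Events dated before the patient's birth date are
    dropped and counted (they violate the record invariant).
    """
    summary = AssemblySummary()
    demo_map: dict[str, tuple[pd.Timestamp, str]] = {}
    if demographics is not None and len(demographics):
        demo_map = {
            r.patient_id: (r.birth_date, r.sex)
            for r in demographics.itertuples(index=False)
        }

    med_groups: dict[str, pd.DataFrame] = {}
    if medications is not None and len(medications):
        med_groups = {
            pid: g[["date", "drug"]].reset_index(drop=True)
            for pid, g in medications.groupby("patient_id", sort=False)
        }

    records: dict[str, PatientRecord] = {}
    for pid, g in diagnoses.groupby("patient_id", sort=True):
        dx = g[["date", "code"]].reset_index(drop=True)
        meds = med_groups.get(pid, _EMPTY_MED)
        birth, sex = demo_map.get(pid, (pd.NaT, "unknown"))
        missing = pid not in demo_map
        if missing:
            summary.missing_demographics.append(pid)
        if not pd.isna(birth):
            ok = dx["date"] > birth
            summary.events_before_birth += int((~ok).sum())
            dx = dx[ok].reset_index(drop=True)
            if len(meds):
                okm = meds["date"] > birth
                summary.events_before_birth += int((~okm).sum())
                meds = meds[okm].reset_index(drop=True)
        if len(dx) == 0:
            continue
        records[pid] = PatientRecord(
            patient_id=pid,
            birth_date=None if pd.isna(birth) else birth,
            sex=sex,
            diagnoses=dx,
            medications=meds,
            demographics_missing=missing,
        )
    summary.n_patients = len(records)
    summary.demographics_without_events = len(set(demo_map) - set(records))
    return records, summary


def write_events(events: pd.DataFrame, path, schema: str) -> None:
    """Write events back to the external CSV schema (ISO dates, byte-stable)."""
    path = Path(path)
    df = events.copy()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    if schema == "diagnosis":
        parts = df["code"].str.partition(":")
        df["code_system"] = parts[0]
        df["code"] = parts[2]
        df = df[DIAGNOSIS_COLUMNS]
    elif schema == "medication":
        df = df[MEDICATION_COLUMNS]
    else:
        raise ValueError(f"unknown schema {schema!r}")
    df.to_csv(path, index=False)


def write_demographics(demographics: pd.DataFrame, path) -> None:
    df = demographics.copy()
    df["birth_date"] = df["birth_date"].dt.strftime("%Y-%m-%d")
    df[DEMOGRAPHICS_COLUMNS].to_csv(path, index=False)
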