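"""Qualifying-fracture identification and anchor-event detection.

A claims-style case definition: fracture-coded diagnoses are scanned
chronologically and a code opens a *new* qualifying event unless a
same-site event already exists within the washout period before it (in
which case it is absorbed as follow-up coding of the earlier fracture).
Aftercare/sequela coding (7th character "D" or "S" in ICD-10-CM style
codes) never opens an event.  The fracture-code catalog is an editable
prefix-pattern file, not a hard-coded list, so site subsets and exclusions
can be swapped without touching code.

For patients with no qualifying fracture the anchor event — the date a
prediction window points at — is the last recorded diagnosis of any kind.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources


import pandas as pd

from .data_model import PatientRecord, split_token

SITES = ("hip", "vertebral", "wrist/forearm", "humerus", "pelvis", "clinical-other")

DEFAULT_WASHOUT_DAYS = 90


@dataclass(frozen=True)
class FractureEvent:
    patient_id: str
    date: pd.Timestamp
    site: str
    is_subsequent: bool
    token: str


@dataclass(frozen=True)
class AnchorEvent:
    """The event a window points at: a qualifying fracture, or — only for
    patients with zero qualifying fractures — the last recorded diagnosis."""

    patient_id: str
    date: pd.Timestamp
    kind: str  # "fracture" | "last_diagnosis"
    fracture: FractureEvent | None = None


class FractureCatalog:
    """Prefix-pattern catalog mapping code tokens to fracture sites.

    Longest matching prefix wins, so ``ICD10:S32.0`` (vertebral) can be
    carved out of a broader ``ICD10:S32`` pelvis block.
    """

    def __init__(self, entries: list[tuple[str, str]]):
        for pattern, site in entries:
            split_token(pattern)  # validates namespacing
            if site not in SITES:
                raise ValueError(f"unknown fracture site {site!r}")
        # longest-first so the first hit is the most specific
        self.entries = sorted(entries, key=lambda e: (-len(e[0]), e[0]))

    @classmethod
    def from_csv(cls, path) -> "FractureCatalog":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls([(r["code_pattern"], r["site"]) for r in rows])

    @classmethod
    def default(cls) -> "FractureCatalog":
        ref = resources.files("crystalbone.data") / "fracture_catalog.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def lookup(self, token: str) -> str | None:
        for pattern, site in self.entries:
            if token.startswith(pattern):
                return site
        return None

    def site_tokens(self) -> dict[str, str]:
        """One representative pattern per site (used by the generator)."""
        out: dict[str, str] = {}
        for pattern, site in sorted(self.entries, key=lambda e: e[0]):
            out.setdefault(site, pattern)
        return out


def is_aftercare_code(token: str) -> bool:
    """ICD-10-CM style 7th-character 'D' (subsequent encounter) or 'S'
    (sequela) on injury codes — follow-up coding, not a new event."""
    system, code = split_token(token)
    if system != "ICD10":
        return False
    compact = code.replace(".", "")
    return len(compact) >= 7 and compact[6] in ("D", "S")


def is_fracture_code(token: str, catalog: FractureCatalog | None = None) -> tuple[bool, str | None]:
    """Membership test against the fracture-code catalog.

    Returns ``(True, site)`` for catalog hits, ``(False, None)`` otherwise.
    Aftercare/sequela forms of catalog codes still return their site; the
    chronological qualifier decides whether they open an event.
    """
    catalog = catalog or _default_catalog()
    site = catalog.lookup(token)
    return (site is not None), site


_CATALOG_CACHE: FractureCatalog | None = None


def _default_catalog() -> FractureCatalog:
    global _CATALOG_CACHE
    if _CATALOG_CACHE is None:
        _CATALOG_CACHE = FractureCatalog.default()
    return _CATALOG_CACHE


def qualify_fracture_events(
    record: PatientRecord,
    washout_days: int = DEFAULT_WASHOUT_DAYS,
    catalog: FractureCatalog | None = None,
) -> list[FractureEvent]:
    """Scan a sorted record and emit qualifying fracture events.

    A fracture-coded diagnosis opens a new event unless a same-site
    qualifying event exists within ``washout_days`` before it; then it is
    absorbed as follow-up coding.  Cross-site codes are always distinct
    events.  ``is_subsequent`` is True iff an earlier qualifying event (any
    site) exists for the patient.  Deterministic given the record.
    """
    if washout_days <= 0:
        raise ValueError("washout_days must be positive")
    catalog = catalog or _default_catalog()
    events: list[FractureEvent] = []
    last_by_site: dict[str, pd.Timestamp] = {}
    washout = pd.Timedelta(days=washout_days)
    for row in record.diagnoses.itertuples(index=False):
        site = catalog.lookup(row.code)
        if site is None:
            continue
        if is_aftercare_code(row.code):
            continue
        prev = last_by_site.get(site)
        if prev is not None and row.date - prev <= washout:
            continue  # absorbed as follow-up coding of the prior event
        events.append(
            FractureEvent(
                patient_id=record.patient_id,
                date=row.date,
                site=site,
                is_subsequent=len(events) > 0,
                token=row.code,
            )
        )
        last_by_site[site] = row.date
    return events


def anchor_events(
    record: PatientRecord,
    fractures: list[FractureEvent] | None = None,
    washout_days: int = DEFAULT_WASHOUT_DAYS,
    catalog: FractureCatalog | None = None,
) -> list[AnchorEvent]:
    """One anchor per qualifying fracture; for fracture-free patients a
    single anchor at the last diagnosis date.  Empty record -> empty list."""
    if len(record.diagnoses) == 0:
        return []
    if fractures is None:
        fractures = qualify_fracture_events(record, washout_days, catalog)
    if fractures:
        return [
            AnchorEvent(record.patient_id, f.date, "fracture", f) for f in fractures
        ]
    return [AnchorEvent(record.patient_id, record.last_dx_date, "last_diagnosis")]
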