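"""Retrospective human-level-performance approximation.

A window counts as "physician-identified risk, worthy of intervention"
when it contains any catalog intervention: a bone-density procedure
(DXA, vertebral fracture assessment, QCT, other densitometry, turnover
markers), an osteoporosis diagnosis (M80/M81/733.0 stems, prefix-matched
so all child codes are included), or one of the listed pharmacologic
treatments.  The *cohort analysis* cross-tabulates model flags against
intervention status and outcome over holdout windows; the *overlap
analysis* scores each treated patient's history up to their first
pharmacologic intervention and measures agreement between model flags and
observed prescribing.

Intervention effects are not adjusted for — the intervention-cohort cells
are confounded by the very treatments that define them, and the reports
carry that caveat as a footnote rather than a correction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .data_model import PatientRecord
from .fractures import FractureEvent
from .windows import Window

CONFOUNDING_FOOTNOTE = (
    "Intervention-cohort cells are confounded by treatment effects: an "
    "intervention can itself modulate fracture risk. Counts are reported "
    "unadjusted."
)


@dataclass(frozen=True)
class InterventionEntry:
    name: str
    kind: str  # "dx" | "proc" | "med"
    pattern: str
    pharmacologic: bool


class InterventionCatalog:
    """The physician-intervention list: prefix patterns over diagnosis /
    procedure tokens and case-insensitive prefixes over drug names."""

    def __init__(self, entries: list[InterventionEntry]):
        for e in entries:
            if e.kind not in ("dx", "proc", "med"):
                raise ValueError(f"unknown intervention kind {e.kind!r}")
            if not e.pattern:
                raise ValueError(f"intervention {e.name!r} has an empty pattern")
        self.entries = list(entries)
        self._code_entries = [e for e in entries if e.kind in ("dx", "proc")]
        self._med_entries = [e for e in entries if e.kind == "med"]

    @classmethod
    def from_csv(cls, path) -> "InterventionCatalog":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls(
            [
                InterventionEntry(
                    name=r["name"],
                    kind=r["kind"],
                    pattern=r["pattern"],
                    pharmacologic=r["pharmacologic"].strip().lower() in ("yes", "true", "1"),
                )
                for r in rows
            ]
        )

    @classmethod
    def default(cls) -> "InterventionCatalog":
        ref = resources.files("crystalbone.data") / "intervention_catalog.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def pharmacologic_only(self) -> "InterventionCatalog":
        return InterventionCatalog([e for e in self.entries if e.pharmacologic])

    def match_code(self, token: str) -> list[InterventionEntry]:
        return [e for e in self._code_entries if token.startswith(e.pattern)]

    def match_drug(self, drug: str) -> list[InterventionEntry]:
        d = drug.lower()
        return [e for e in self._med_entries if d.startswith(e.pattern.lower())]


def detect_interventions(
    record: PatientRecord,
    window: Window,
    catalog: InterventionCatalog,
    history_days: int = 730,
) -> tuple[bool, list[InterventionEntry]]:
    """Scan the window span (same half-open span as the code sequence —
    an intervention on the anchor day itself is outside the window) for
    catalog matches in the diagnosis/procedure and medication streams."""
    end = window.window_end
    start = end - pd.Timedelta(days=history_days)
    matched: dict[str, InterventionEntry] = {}
    dx = record.diagnoses
    for row in dx[(dx["date"] > start) & (dx["date"] <= end)].itertuples(index=False):
        for e in catalog.match_code(row.code):
            matched[e.name] = e
    med = record.medications
    if len(med):
        for row in med[(med["date"] > start) & (med["date"] <= end)].itertuples(index=False):
            for e in catalog.match_drug(row.drug):
                matched[e.name] = e
    entries = [matched[k] for k in sorted(matched)]
    return bool(entries), entries


def _pct(num: int, den: int) -> float | None:
    return round(100.0 * num / den, 1) if den else None


@dataclass
class CohortAnalysisReport:
    """The intervention x outcome x flag cross-tabulation with row
    percentages, plus the unique-event roll-up for the no-intervention
    fracture cell."""

    cells: dict  # (intervention, outcome) -> {"total", "flag", "no_flag"}
    unique_events_total: int
    unique_events_flagged: int
    footnote: str = CONFOUNDING_FOOTNOTE

    @classmethod
    def from_counts(
        cls,
        no_int_fracture_total: int,
        no_int_fracture_flagged: int,
        no_int_nonfracture_total: int,
        no_int_nonfracture_flagged: int,
        int_fracture_total: int,
        int_fracture_flagged: int,
        int_nonfracture_total: int,
        int_nonfracture_flagged: int,
        unique_events_total: int = 0,
        unique_events_flagged: int = 0,
    ) -> "CohortAnalysisReport":
        cells = {}
        for key, total, flagged in (
            (("no_intervention", "fracture"), no_int_fracture_total, no_int_fracture_flagged),
            (("no_intervention", "nonfracture"), no_int_nonfracture_total, no_int_nonfracture_flagged),
            (("intervention", "fracture"), int_fracture_total, int_fracture_flagged),
            (("intervention", "nonfracture"), int_nonfracture_total, int_nonfracture_flagged),
        ):
            if flagged > total:
                raise ValueError(f"flagged count exceeds cell total in {key}")
            cells[key] = {"total": total, "flag": flagged, "no_flag": total - flagged}
        return cls(cells, unique_events_total, unique_events_flagged)

    # ---- derived quantities -------------------------------------------

    @property
    def total_windows(self) -> int:
        return sum(c["total"] for c in self.cells.values())

    def cohort_total(self, intervention: str) -> int:
        return sum(
            c["total"] for k, c in self.cells.items() if k[0] == intervention
        )

    def cohort_share_pct(self, intervention: str) -> float | None:
        return _pct(self.cohort_total(intervention), self.total_windows)

    def outcome_share_pct(self, intervention: str, outcome: str) -> float | None:
        return _pct(self.cells[(intervention, outcome)]["total"], self.cohort_total(intervention))

    def flag_pct(self, intervention: str, outcome: str) -> float | None:
        c = self.cells[(intervention, outcome)]
        return _pct(c["flag"], c["total"])

    def no_flag_pct(self, intervention: str, outcome: str) -> float | None:
        c = self.cells[(intervention, outcome)]
        return _pct(c["no_flag"], c["total"])

    @property
    def unique_event_flag_pct(self) -> float | None:
        return _pct(self.unique_events_flagged, self.unique_events_total)

    def to_dict(self) -> dict:
        out = {
            "total_windows": self.total_windows,
            "unique_events_total": self.unique_events_total,
            "unique_events_flagged": self.unique_events_flagged,
            "unique_event_flag_pct": self.unique_event_flag_pct,
            "footnote": self.footnote,
            "cells": {},
        }
        for (iv, oc), c in self.cells.items():
            out["cells"][f"{iv}/{oc}"] = {
                **c,
                "flag_pct": self.flag_pct(iv, oc),
                "no_flag_pct": self.no_flag_pct(iv, oc),
            }
        return out

    def to_text(self) -> str:
        lines = [
            f"{'Cohort':34s}{'Windows, n (%)':>20s}{'Flag, n (%)':>20s}{'No flag, n (%)':>20s}",
            f"Total{'':29s}{self.total_windows:>12,} (100){'—':>18s}{'—':>20s}",
        ]
        for iv in ("no_intervention", "intervention"):
            share = self.cohort_share_pct(iv)
            lines.append(
                f"  {iv:32s}{self.cohort_total(iv):>12,} ({share}){'—':>12s}{'—':>20s}"
            )
            for oc in ("fracture", "nonfracture"):
                c = self.cells[(iv, oc)]
                lines.append(
                    f"    {oc:30s}{c['total']:>12,} ({self.outcome_share_pct(iv, oc)})"
                    f"{c['flag']:>12,} ({self.flag_pct(iv, oc)})"
                    f"{c['no_flag']:>12,} ({self.no_flag_pct(iv, oc)})"
                )
        lines.append(f"note: {self.footnote}")
        return "\n".join(lines)


def cohort_analysis(
    windows: list[Window],
    flags,
    records: dict[str, PatientRecord],
    catalog: InterventionCatalog | None = None,
    history_days: int = 730,
) -> CohortAnalysisReport:
    """Partition holdout windows by intervention status and outcome and
    cross-tabulate model flags.

    ``flags`` is the per-window boolean flag sequence (aligned with
    ``windows``).  The unique-event roll-up counts anchor events with at
    least one window in the no-intervention fracture cell, and among them
    those with at least one flagged window in that cell.
    """
    catalog = catalog or InterventionCatalog.default()
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(windows):
        raise ValueError("flags and windows must align")
    counts = {
        (iv, oc): {"total": 0, "flag": 0}
        for iv in ("no_intervention", "intervention")
        for oc in ("fracture", "nonfracture")
    }
    events: dict[tuple[str, str], bool] = {}
    for w, fl in zip(windows, flags):
        any_iv, _ = detect_interventions(records[w.patient_id], w, catalog, history_days)
        iv = "intervention" if any_iv else "no_intervention"
        oc = "fracture" if w.label else "nonfracture"
        counts[(iv, oc)]["total"] += 1
        counts[(iv, oc)]["flag"] += bool(fl)
        if iv == "no_intervention" and oc == "fracture":
            key = (w.patient_id, w.anchor.date.isoformat())
            events[key] = events.get(key, False) or bool(fl)
    return CohortAnalysisReport.from_counts(
        counts[("no_intervention", "fracture")]["total"],
        counts[("no_intervention", "fracture")]["flag"],
        counts[("no_intervention", "nonfracture")]["total"],
        counts[("no_intervention", "nonfracture")]["flag"],
        counts[("intervention", "fracture")]["total"],
        counts[("intervention", "fracture")]["flag"],
        counts[("intervention", "nonfracture")]["total"],
        counts[("intervention", "nonfracture")]["flag"],
        unique_events_total=len(events),
        unique_events_flagged=sum(events.values()),
    )


@dataclass
class OverlapAnalysisReport:
    """Agreement between model flags and first pharmacologic treatment."""

    n_treated: int
    n_sufficient_history: int
    n_flagged: int
    n_flagged_fractured: int
    n_fractured_total: int
    n_fractured_flagged: int
    footnote: str = CONFOUNDING_FOOTNOTE

    def __post_init__(self):
        if not (
            self.n_flagged <= self.n_sufficient_history <= self.n_treated
            and self.n_flagged_fractured <= self.n_flagged
            and self.n_fractured_flagged <= self.n_fractured_total
        ):
            raise ValueError("overlap-analysis counts do not nest")

    @classmethod
    def from_counts(cls, **kw) -> "OverlapAnalysisReport":
        return cls(**kw)

    @property
    def flag_pct(self) -> float | None:
        """% of sufficient-history treated patients flagged by the model."""
        return _pct(self.n_flagged, self.n_sufficient_history)

    @property
    def flagged_fracture_pct(self) -> float | None:
        """% of flagged patients fracturing within the horizon."""
        return _pct(self.n_flagged_fractured, self.n_flagged)

    @property
    def fractured_flag_pct(self) -> float | None:
        """% of fracturing treated patients the model flagged."""
        return _pct(self.n_fractured_flagged, self.n_fractured_total)

    def to_dict(self) -> dict:
        return {
            "n_treated": self.n_treated,
            "n_sufficient_history": self.n_sufficient_history,
            "n_flagged": self.n_flagged,
            "flag_pct": self.flag_pct,
            "n_flagged_fractured": self.n_flagged_fractured,
            "flagged_fracture_pct": self.flagged_fracture_pct,
            "n_fractured_total": self.n_fractured_total,
            "n_fractured_flagged": self.n_fractured_flagged,
            "fractured_flag_pct": self.fractured_flag_pct,
            "footnote": self.footnote,
        }


def overlap_analysis(
    records: dict[str, PatientRecord],
    fractures_by_patient: dict[str, list[FractureEvent]],
    score_windows,
    catalog: InterventionCatalog | None = None,
    threshold: float = 0.5,
    horizon_days: int = 730,
    history_days: int = 730,
    cohort_tag: str = "pan_therapeutic",
) -> OverlapAnalysisReport:
    """Score each treated patient's history up to their first pharmacologic
    intervention.

    ``score_windows`` is a callable mapping a list of :class:`Window` to
    probabilities (a fitted model's ``predict_proba``).  For each patient
    with a pharmacologic catalog drug, one window is built ending the day
    before the first such prescription, subject to the usual full-history
    coverage requirement; insufficient-history patients are counted and
    excluded.  Fracture-within-horizon is measured from the intervention
    date.
    """
    catalog = (catalog or InterventionCatalog.default()).pharmacologic_only()
    from .fractures import AnchorEvent  # local to avoid cycle at import time

    treated: list[tuple[str, pd.Timestamp]] = []
    for pid in sorted(records):
        rec = records[pid]
        if not len(rec.medications):
            continue
        hits = [
            row.date
            for row in rec.medications.itertuples(index=False)
            if catalog.match_drug(row.drug)
        ]
        if hits:
            treated.append((pid, min(hits)))

    eligible: list[Window] = []
    frac_within: list[bool] = []
    for pid, t0 in treated:
        rec = records[pid]
        end = t0 - pd.Timedelta(days=1)
        start = end - pd.Timedelta(days=history_days)
        if rec.first_dx_date is None or rec.first_dx_date > start:
            continue
        dx = rec.diagnoses
        mask = (dx["date"] > start) & (dx["date"] <= end)
        codes = dx.loc[mask, "code"].tolist()
        frs = fractures_by_patient.get(pid, [])
        fractured = any(t0 < f.date <= t0 + pd.Timedelta(days=horizon_days) for f in frs)
        anchor = AnchorEvent(pid, t0, "fracture" if fractured else "last_diagnosis")
        age = rec.age_at(end)
        eligible.append(
            Window(
                patient_id=pid,
                anchor=anchor,
                window_end=end,
                codes=codes,
                label=fractured,
                time_to_event=1,
                age=age if age is not None else float("nan"),
                sex=rec.sex,
                dx_count=len(codes),
                cohort_tag=cohort_tag,
            )
        )
        frac_within.append(fractured)

    if eligible:
        probs = np.asarray(score_windows(eligible), dtype=float)
        flagged = probs >= threshold
    else:
        flagged = np.zeros(0, dtype=bool)
    frac = np.asarray(frac_within, dtype=bool)
    return OverlapAnalysisReport(
        n_treated=len(treated),
        n_sufficient_history=len(eligible),
        n_flagged=int(flagged.sum()),
        n_flagged_fractured=int((flagged & frac).sum()),
        n_fractured_total=int(frac.sum()),
        n_fractured_flagged=int((frac & flagged).sum()),
    )
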