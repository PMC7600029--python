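"""Cohort eligibility, the sliding-window algorithm, vocabulary, splits.

Every anchor event can carry up to ``max_windows`` candidate windows whose
ends step back from the anchor in ``stride_days`` increments.  Each window
is the chronologically ordered diagnosis-code sequence in the 730 days up
to its end, labeled positive iff a qualifying fracture falls inside the
forward horizon.  Candidates are dropped when the patient's history does
not cover the full span, or when a *different* qualifying fracture of the
same patient falls inside the window span or the horizon (ambiguous
coverage).  Window ends earlier than one horizon before a fracture anchor
therefore survive with a negative label, which is how fracture patients
contribute non-fracture windows.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DAYS_PER_YEAR, PatientRecord
from .fractures import AnchorEvent, FractureEvent

DEFAULT_HISTORY_DAYS = 730
DEFAULT_HORIZON_DAYS = 730
DEFAULT_MAX_WINDOWS = 5
DEFAULT_STRIDE_DAYS = 183
DEFAULT_MIN_AGE = 50.0
DEFAULT_MIN_COUNT = 5

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"


@dataclass
class Window:
    """A labeled 2-year code sequence ending at ``window_end``."""

    patient_id: str
    anchor: AnchorEvent
    window_end: pd.Timestamp
    codes: list[str]
    label: bool
    time_to_event: int  # days from window_end to the anchor date
    age: float
    sex: str
    dx_count: int  # diagnosis codes in the span, before any truncation
    cohort_tag: str = "pan_therapeutic"
    source: str = "natural"  # "natural" | "oversampled"

    @property
    def window_id(self) -> str:
        return f"{self.patient_id}@{self.window_end.date().isoformat()}"


@dataclass
class CohortSelection:
    eligible: list[tuple[PatientRecord, AnchorEvent]]
    exclusions: dict[str, int] = field(default_factory=dict)


def select_cohort(
    records: dict[str, PatientRecord],
    anchors: dict[str, list[AnchorEvent]],
    min_age: float = DEFAULT_MIN_AGE,
    min_history_days: int = DEFAULT_HISTORY_DAYS,
) -> CohortSelection:
    """Keep anchors where the patient is at least ``min_age`` at the anchor
    and has at least ``min_history_days`` of history before it."""
    eligible: list[tuple[PatientRecord, AnchorEvent]] = []
    excl: Counter[str] = Counter()
    history = pd.Timedelta(days=min_history_days)
    for pid in sorted(anchors):
        record = records[pid]
        for anchor in anchors[pid]:
            age = record.age_at(anchor.date)
            if age is None:
                excl["unknown_age"] += 1
                continue
            if age < min_age:
                excl["under_age"] += 1
                continue
            if record.first_dx_date is None or record.first_dx_date > anchor.date - history:
                excl["insufficient_history"] += 1
                continue
            eligible.append((record, anchor))
    return CohortSelection(eligible=eligible, exclusions=dict(excl))


def build_windows(
    anchor: AnchorEvent,
    record: PatientRecord,
    fractures: list[FractureEvent],
    horizon_days: int = DEFAULT_HORIZON_DAYS,
    max_windows: int = DEFAULT_MAX_WINDOWS,
    stride_days: int = DEFAULT_STRIDE_DAYS,
    history_days: int = DEFAULT_HISTORY_DAYS,
    cohort_tag: str = "pan_therapeutic",
) -> list[Window]:
    """Build the surviving windows for one eligible anchor.

    Candidate k (k = 0..max_windows-1) ends at ``anchor - 1 - k*stride``.
    The span is the half-open interval ``(end - history_days, end]`` — the
    anchor day itself is excluded so a fracture's own coding never leaks
    into its window.
    """
    out: list[Window] = []
    dates = record.diagnoses["date"]
    first_dx = record.first_dx_date
    frac_dates = [f.date for f in fractures]
    own = anchor.fracture.date if anchor.fracture is not None else None
    for k in range(max_windows):
        end = anchor.date - pd.Timedelta(days=1 + k * stride_days)
        start = end - pd.Timedelta(days=history_days)
        if first_dx is None or first_dx > start:
            continue  # incomplete coverage of the span
        # a different fracture inside the span or the horizon makes the
        # window ambiguously attributable to two events -> dropped
        horizon_end = end + pd.Timedelta(days=horizon_days)
        other = [
            d for d in frac_dates
            if d != own and (start < d <= end or end < d <= horizon_end)
        ]
        if other:
            continue
        label = any(end < d <= horizon_end for d in frac_dates)
        mask = (dates > start) & (dates <= end)
        codes = record.diagnoses.loc[mask, "code"].tolist()
        out.append(
            Window(
                patient_id=record.patient_id,
                anchor=anchor,
                window_end=end,
                codes=codes,
                label=label,
                time_to_event=int((anchor.date - end).days),
                age=record.age_at(end) if record.age_at(end) is not None else float("nan"),
                sex=record.sex,
                dx_count=len(codes),
                cohort_tag=cohort_tag,
            )
        )
    return out


def build_all_windows(
    selection: CohortSelection,
    fractures_by_patient: dict[str, list[FractureEvent]],
    cohort_tag: str = "pan_therapeutic",
    **kwargs,
) -> list[Window]:
    """Windows for every eligible anchor, de-duplicated per patient by
    window end (two anchors of one patient can propose the same end)."""
    seen: set[tuple[str, pd.Timestamp]] = set()
    out: list[Window] = []
    for record, anchor in selection.eligible:
        frs = fractures_by_patient.get(record.patient_id, [])
        for w in build_windows(anchor, record, frs, cohort_tag=cohort_tag, **kwargs):
            key = (w.patient_id, w.window_end)
            if key in seen:
                continue
            seen.add(key)
            out.append(w)
    return out


class Vocabulary:
    """Token -> contiguous integer index, frequency-then-lexicographic.

    Index 0 is padding, index 1 the unknown token; real tokens start at 2.
    Only tokens occurring at least ``min_count`` times in the reference
    corpus are indexed; everything else maps to the unknown token.
    """

    def __init__(self, counts: dict[str, int], min_count: int = DEFAULT_MIN_COUNT):
        kept = {t: c for t, c in counts.items() if c >= min_count}
        ordered = sorted(kept, key=lambda t: (-kept[t], t))
        self.min_count = min_count
        self.counts = kept
        self.index = {PAD_TOKEN: 0, UNK_TOKEN: 1}
        for i, tok in enumerate(ordered, start=2):
            self.index[tok] = i
        self.tokens = [PAD_TOKEN, UNK_TOKEN] + ordered

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @property
    def pad_index(self) -> int:
        return 0

    @property
    def unk_index(self) -> int:
        return 1

    def encode(self, tokens: list[str]) -> np.ndarray:
        unk = self.unk_index
        return np.array([self.index.get(t, unk) for t in tokens], dtype=np.int64)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# min_count={self.min_count}\n")
            for tok in self.tokens[2:]:
                fh.write(f"{tok}\t{self.counts[tok]}\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        counts: dict[str, int] = {}
        min_count = DEFAULT_MIN_COUNT
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    if "min_count=" in line:
                        min_count = int(line.split("min_count=")[1])
                    continue
                tok, c = line.split("\t")
                counts[tok] = int(c)
        return cls(counts, min_count=min_count)


def build_vocabulary(windows: list[Window], min_count: int = DEFAULT_MIN_COUNT) -> Vocabulary:
    """Count token occurrences across the reference windows and index those
    meeting the minimum count.  Raises on an empty corpus."""
    counts: Counter[str] = Counter()
    for w in windows:
        counts.update(w.codes)
    if not counts:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    return Vocabulary(dict(counts), min_count=min_count)


@dataclass(frozen=True)
class SplitPlan:
    train_patients: frozenset[str]
    holdout_patients: frozenset[str]
    ratio: float
    seed: int


def split_train_holdout(windows: list[Window], ratio: float = 0.7, seed: int = 0) -> SplitPlan:
    """Patient-level random partition: no patient ever contributes windows
    to both sides.  Deterministic given the seed."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    patients = sorted({w.patient_id for w in windows})
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(patients))
    n_train = int(round(ratio * len(patients)))
    train = frozenset(patients[i] for i in perm[:n_train])
    holdout = frozenset(patients[i] for i in perm[n_train:])
    return SplitPlan(train, holdout, ratio, seed)


def apply_split(windows: list[Window], plan: SplitPlan) -> tuple[list[Window], list[Window]]:
    train = [w for w in windows if w.patient_id in plan.train_patients]
    holdout = [w for w in windows if w.patient_id in plan.holdout_patients]
    return train, holdout


def oversample_balance(
    train_windows: list[Window],
    fracture_pool: list[Window],
    seed: int = 0,
) -> list[Window]:
    """Append fracture windows sampled from the bone-health pool until the
    training set is balanced 50:50.  Samples with replacement when the pool
    is smaller than the deficit.  The holdout set is never touched."""
    n_pos = sum(w.label for w in train_windows)
    n_neg = len(train_windows) - n_pos
    deficit = n_neg - n_pos
    if deficit <= 0:
        return list(train_windows)
    if not fracture_pool:
        raise ValueError("imbalanced training set but empty oversampling pool")
    if any(not w.label for w in fracture_pool):
        raise ValueError("oversampling pool must contain only fracture windows")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(fracture_pool), size=deficit, replace=deficit > len(fracture_pool))
    sampled = []
    for i in idx:
        w = fracture_pool[int(i)]
        sampled.append(
            Window(
                patient_id=w.patient_id,
                anchor=w.anchor,
                window_end=w.window_end,
                codes=list(w.codes),
                label=w.label,
                time_to_event=w.time_to_event,
                age=w.age,
                sex=w.sex,
                dx_count=w.dx_count,
                cohort_tag=w.cohort_tag,
                source="oversampled",
            )
        )
    return list(train_windows) + sampled


def windows_to_frame(windows: list[Window]) -> pd.DataFrame:
    """One row per window, sequence space-joined (the on-disk schema)."""
    return pd.DataFrame(
        {
            "patient_id": [w.patient_id for w in windows],
            "window_end": [w.window_end.date().isoformat() for w in windows],
            "label": [int(w.label) for w in windows],
            "time_to_event": [w.time_to_event for w in windows],
            "age": [round(w.age, 4) for w in windows],
            "sex": [w.sex for w in windows],
            "dx_count": [w.dx_count for w in windows],
            "cohort_tag": [w.cohort_tag for w in windows],
            "source": [w.source for w in windows],
            "codes": [" ".join(w.codes) for w in windows],
        }
    )
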