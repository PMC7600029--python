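"""Synthetic EHR cohort generator.

Emulates the statistical structure the fracture-risk pipeline assumes —
multi-year per-patient streams of namespaced diagnosis codes with a
Zipf-like frequency distribution, scheduled qualifying fractures whose
share of anchor events is calibrated to a target incidence among patients
over 50, elevated pre-fracture frequencies of designated risk-signal
codes, and bone-health interventions (densitometry procedure codes,
osteoporosis diagnoses, anti-resorptive/anabolic drugs) injected before a
configurable fraction of fractures — so every downstream stage is testable
without any external data.

Fracture probability is a per-patient hazard ``exp(b*(age-70) + frailty)``
scaled by a constant found by bisection so that the *expected* fracture
share of anchor events in the over-50 population equals the configured
target; age is therefore a genuine, baseline-recoverable risk factor.  All
randomness flows from one seeded generator; identical config + seed gives
byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import DAYS_PER_YEAR
from .fractures import (
    AnchorEvent,
    FractureCatalog,
    FractureEvent,
    qualify_fracture_events,
)
from .data_model import PatientRecord

COHORT_KINDS = ("pan_therapeutic", "bone_health")

DEFAULT_INCIDENCE = {"pan_therapeutic": 0.085, "bone_health": 0.39}

#: one representative initial-encounter code per fracture site
SITE_CODES = {
    "hip": "ICD10:S72.001A",
    "vertebral": "ICD10:S22.000A",
    "wrist/forearm": "ICD10:S52.501A",
    "humerus": "ICD10:S42.201A",
    "pelvis": "ICD10:S32.301A",
    "clinical-other": "ICD10:S82.001A",
}
SITE_WEIGHTS = {
    "hip": 0.25,
    "vertebral": 0.20,
    "wrist/forearm": 0.25,
    "humerus": 0.12,
    "pelvis": 0.08,
    "clinical-other": 0.10,
}

PHARM_DRUGS = (
    "alendronate",
    "risedronate",
    "ibandronate",
    "zoledronic acid",
    "denosumab",
    "teriparatide",
    "raloxifene",
)
BENIGN_DRUGS = ("lisinopril", "metformin", "atorvastatin", "levothyroxine")

DXA_TOKEN = "CPT:77080"
OSTEO_DX_TOKEN = "ICD10:M81.0"


def default_signal_codes() -> dict[str, float]:
    """Mid-frequency background codes whose rate triples pre-fracture."""
    return {f"SYN:C{r:04d}": 3.0 for r in range(15, 39, 2)}


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 1000
    cohort_kind: str = "pan_therapeutic"
    study_period: tuple[str, str] = ("2007-01-01", "2018-12-31")
    mean_events_per_patient_year: float = 12.0
    vocabulary_size: int = 2000
    target_fracture_incidence: float | None = None  # default by cohort kind
    signal_codes: dict[str, float] | None = None  # None -> defaults
    signal_lead_time: int = 540
    intervention_rate: float = 0.35
    multi_fracture_rate: float = 0.10
    age_coeff: float = 0.06  # log-hazard per year of age at the anchor
    sex_coeff: float = 0.60  # female log-hazard
    frailty_sd: float = 0.30
    id_prefix: str | None = None  # default: PT/BH by cohort kind
    seed: int = 0

    @property
    def patient_prefix(self) -> str:
        if self.id_prefix is not None:
            return self.id_prefix
        return "PT" if self.cohort_kind == "pan_therapeutic" else "BH"

    @property
    def incidence(self) -> float:
        if self.target_fracture_incidence is not None:
            return self.target_fracture_incidence
        return DEFAULT_INCIDENCE[self.cohort_kind]

    def validate(self) -> None:
        if self.cohort_kind not in COHORT_KINDS:
            raise ValueError(f"unknown cohort_kind {self.cohort_kind!r}")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError("target_fracture_incidence must lie in [0, 1]")
        if self.mean_events_per_patient_year <= 0:
            raise ValueError("mean_events_per_patient_year must be positive")
        if self.vocabulary_size <= 0:
            raise ValueError("vocabulary_size must be positive")


@dataclass
class GroundTruth:
    """What the generator actually scheduled, for oracle recomputation."""

    fractures: pd.DataFrame  # patient_id, date, site
    interventions: pd.DataFrame  # patient_id, date, kind, name, pharmacologic


@dataclass
class CohortData:
    diagnoses: pd.DataFrame
    medications: pd.DataFrame
    demographics: pd.DataFrame
    ground_truth: GroundTruth
    config: GeneratorConfig


def _empty_cohort(config: GeneratorConfig) -> CohortData:
    dx = pd.DataFrame({"patient_id": pd.Series(dtype=str),
                       "date": pd.Series(dtype="datetime64[ns]"),
                       "code": pd.Series(dtype=str)})
    med = pd.DataFrame({"patient_id": pd.Series(dtype=str),
                        "date": pd.Series(dtype="datetime64[ns]"),
                        "drug": pd.Series(dtype=str)})
    demo = pd.DataFrame({"patient_id": pd.Series(dtype=str),
                         "birth_date": pd.Series(dtype="datetime64[ns]"),
                         "sex": pd.Series(dtype=str)})
    gt = GroundTruth(
        fractures=pd.DataFrame(columns=["patient_id", "date", "site"]),
        interventions=pd.DataFrame(columns=["patient_id", "date", "kind", "name", "pharmacologic"]),
    )
    return CohortData(dx, med, demo, gt, config)


def _calibrate_hazard_scale(
    hazard: np.ndarray,
    k_events: np.ndarray,
    over50_frac: np.ndarray,
    over50_nonfrac: np.ndarray,
    target: float,
) -> float:
    """Find c so that E[fracture share of over-50 anchor events] = target,
    with per-patient fracture probability min(c*hazard, 0.95).

    The expectation is g(c) = sum(p*k | would-be-fracture counted) /
    (same + sum(1-p | non-fracture anchor counted)); g is monotone in c,
    so bisection converges unconditionally.
    """
    if target <= 0:
        return 0.0

    def gap(c: float) -> float:
        p = np.minimum(c * hazard, 0.95)
        num = float(np.sum(p * k_events * over50_frac))
        den = num + float(np.sum((1.0 - p) * over50_nonfrac))
        if den == 0:
            return -target
        return num / den - target

    lo, hi = 0.0, 1.0
    while gap(hi) < 0 and hi < 1e6:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if gap(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: GeneratorConfig) -> CohortData:
    """Generate one synthetic cohort.  See the module docstring for the
    statistical construction; deterministic given config + seed."""
    config.validate()
    if config.n_patients == 0:
        return _empty_cohort(config)

    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    period_start = pd.Timestamp(config.study_period[0])
    period_end = pd.Timestamp(config.study_period[1])
    total_days = (period_end - period_start).days
    if total_days < 3 * 365 + 1:
        raise ValueError("study period must cover at least 3 years")

    pids = np.array([f"{config.patient_prefix}{i:07d}" for i in range(n)])

    max_span = min(10 * 365, total_days)
    span = rng.integers(3 * 365, max_span + 1, size=n)
    start_off = (rng.random(n) * (total_days - span + 1)).astype(np.int64)
    obs_start = start_off
    obs_end = start_off + span  # day offsets from period_start

    # ages: most patients well past 50 through the whole span, a small
    # young tail to exercise the age filter
    age0 = np.clip(rng.normal(68.0, 9.0, size=n), 52.0, 92.0)
    young = rng.random(n) < 0.05
    age0[young] = rng.uniform(42.0, 49.5, size=int(young.sum()))
    birth_off = obs_start - np.round(age0 * DAYS_PER_YEAR).astype(np.int64)

    p_female = 0.75 if config.cohort_kind == "bone_health" else 0.55
    sex = np.where(rng.random(n) < p_female, "female", "male")

    # provisional first-fracture date: late enough for 2 years of history
    lead = 800
    d_frac_off = obs_start + lead + (rng.random(n) * (span - lead - 10)).astype(np.int64)
    age_at_frac = (d_frac_off - birth_off) / DAYS_PER_YEAR
    age_at_end = (obs_end - birth_off) / DAYS_PER_YEAR
    over50_frac = (age_at_frac >= 50.0).astype(float)
    over50_nonfrac = (age_at_end >= 50.0).astype(float)

    multi = rng.random(n) < config.multi_fracture_rate
    room = (obs_end - d_frac_off) >= 240
    k_events = 1.0 + (multi & room)

    frailty = rng.normal(0.0, config.frailty_sd, size=n)
    age_mid = age0 + span / (2.0 * DAYS_PER_YEAR)
    hazard = np.exp(
        config.age_coeff * (age_mid - 70.0)
        + config.sex_coeff * (sex == "female")
        + frailty
    )

    c = _calibrate_hazard_scale(hazard, k_events, over50_frac, over50_nonfrac,
                                config.incidence)
    p_frac = np.minimum(c * hazard, 0.95)
    is_frac = rng.random(n) < p_frac

    # ---- scheduled fracture events -------------------------------------
    sites = np.array(list(SITE_WEIGHTS))
    site_p = np.array(list(SITE_WEIGHTS.values()))
    site_p = site_p / site_p.sum()

    ev_pid: list[np.ndarray] = []
    ev_off: list[np.ndarray] = []
    ev_site: list[np.ndarray] = []

    idx1 = np.where(is_frac)[0]
    ev_pid.append(pids[idx1])
    ev_off.append(d_frac_off[idx1])
    ev_site.append(rng.choice(sites, size=len(idx1), p=site_p))

    idx2 = np.where(is_frac & multi & room)[0]
    if len(idx2):
        gap_max = obs_end[idx2] - d_frac_off[idx2] - 20
        gap = 200 + (rng.random(len(idx2)) * np.maximum(gap_max - 200, 1)).astype(np.int64)
        ev_pid.append(pids[idx2])
        ev_off.append(d_frac_off[idx2] + gap)
        ev_site.append(rng.choice(sites, size=len(idx2), p=site_p))

    frac_pid = np.concatenate(ev_pid)
    frac_off = np.concatenate(ev_off)
    frac_site = np.concatenate(ev_site)

    # ---- background diagnosis stream -----------------------------------
    rate_daily = config.mean_events_per_patient_year / DAYS_PER_YEAR
    n_codes = np.maximum(1, rng.poisson(rate_daily * span))
    total_codes = int(n_codes.sum())
    bg_pid = np.repeat(pids, n_codes)
    bg_start = np.repeat(obs_start, n_codes)
    bg_span = np.repeat(span, n_codes)
    bg_off = bg_start + (rng.random(total_codes) * bg_span).astype(np.int64)

    V = config.vocabulary_size
    ranks = np.arange(1, V + 1, dtype=float)
    zipf_p = 1.0 / (ranks + 2.7) ** 1.07
    zipf_p /= zipf_p.sum()
    token_table = np.array([f"SYN:C{i:04d}" for i in range(V)])
    bg_tok = token_table[rng.choice(V, size=total_codes, p=zipf_p)]

    # ---- pre-fracture signal-code enrichment ---------------------------
    signal = config.signal_codes if config.signal_codes is not None else default_signal_codes()
    sig_pid: list[str] = []
    sig_off: list[int] = []
    sig_tok: list[str] = []
    if signal and len(frac_pid):
        pid_to_start = dict(zip(pids, obs_start))
        ev_start = np.array([pid_to_start[p] for p in frac_pid])
        lead_eff = np.minimum(config.signal_lead_time, frac_off - ev_start)
        base_p = dict(zip(token_table, zipf_p))
        for tok, rr in sorted(signal.items()):
            p_tok = base_p.get(tok)
            if p_tok is None:
                raise ValueError(f"signal code {tok!r} outside the synthetic vocabulary")
            lam = max(rr - 1.0, 0.0) * p_tok * rate_daily * lead_eff
            extra = rng.poisson(lam)
            rep = np.repeat(np.arange(len(frac_pid)), extra)
            if len(rep) == 0:
                continue
            offs = frac_off[rep] - 1 - (rng.random(len(rep)) * (lead_eff[rep] - 1)).astype(np.int64)
            sig_pid.extend(frac_pid[rep])
            sig_off.extend(offs)
            sig_tok.extend([tok] * len(rep))

    # ---- fracture coding: initial encounter + follow-up aftercare ------
    fr_tok = np.array([SITE_CODES[s] for s in frac_site])
    fu_pid: list[str] = []
    fu_off: list[int] = []
    fu_tok: list[str] = []
    has_fu = rng.random(len(frac_pid)) < 0.7
    for i in np.where(has_fu)[0]:
        n_fu = int(rng.integers(1, 3))
        for _ in range(n_fu):
            fu_pid.append(frac_pid[i])
            fu_off.append(int(frac_off[i]) + int(rng.integers(10, 81)))
            fu_tok.append(fr_tok[i][:-1] + "D")

    # ---- interventions -------------------------------------------------
    iv_rows: list[tuple[str, int, str, str, bool]] = []
    dx_extra_pid: list[str] = []
    dx_extra_off: list[int] = []
    dx_extra_tok: list[str] = []
    med_pid: list[str] = []
    med_off: list[int] = []
    med_drug: list[str] = []

    treated_frac = rng.random(n) < config.intervention_rate
    for i in np.where(is_frac & treated_frac)[0]:
        d = int(d_frac_off[i])
        off = d - int(rng.integers(120, 701))
        dx_extra_pid.append(pids[i]); dx_extra_off.append(off); dx_extra_tok.append(DXA_TOKEN)
        iv_rows.append((pids[i], off, "proc", "dxa", False))
        if rng.random() < 0.6:
            drug = str(rng.choice(PHARM_DRUGS))
            off = d - int(rng.integers(60, 601))
            med_pid.append(pids[i]); med_off.append(off); med_drug.append(drug)
            iv_rows.append((pids[i], off, "med", drug, True))
        if rng.random() < 0.4:
            off = d - int(rng.integers(100, 701))
            dx_extra_pid.append(pids[i]); dx_extra_off.append(off); dx_extra_tok.append(OSTEO_DX_TOKEN)
            iv_rows.append((pids[i], off, "dx", "osteoporosis", False))

    treated_non = rng.random(n) < config.intervention_rate / 3.0
    for i in np.where(~is_frac & treated_non)[0]:
        lo = int(obs_start[i]) + 800
        hi = int(obs_end[i]) - 30
        if hi <= lo:
            continue
        off = int(rng.integers(lo, hi))
        dx_extra_pid.append(pids[i]); dx_extra_off.append(off); dx_extra_tok.append(DXA_TOKEN)
        iv_rows.append((pids[i], off, "proc", "dxa", False))
        if rng.random() < 0.3:
            drug = str(rng.choice(PHARM_DRUGS))
            med_pid.append(pids[i]); med_off.append(off + int(rng.integers(0, 60))); med_drug.append(drug)
            iv_rows.append((pids[i], med_off[-1], "med", drug, True))

    # benign background medications
    has_benign = rng.random(n) < 0.3
    for i in np.where(has_benign)[0]:
        for _ in range(int(rng.integers(1, 4))):
            med_pid.append(pids[i])
            med_off.append(int(obs_start[i]) + int(rng.random() * span[i]))
            med_drug.append(str(rng.choice(BENIGN_DRUGS)))

    # ---- assemble tables ----------------------------------------------
    def to_dates(off) -> pd.Series:
        return period_start + pd.to_timedelta(np.asarray(off, dtype=np.int64), unit="D")

    dx = pd.DataFrame(
        {
            "patient_id": np.concatenate([bg_pid, frac_pid, np.array(fu_pid, dtype=object),
                                          np.array(sig_pid, dtype=object),
                                          np.array(dx_extra_pid, dtype=object)]),
            "date": to_dates(np.concatenate([bg_off, frac_off,
                                             np.array(fu_off, dtype=np.int64),
                                             np.array(sig_off, dtype=np.int64),
                                             np.array(dx_extra_off, dtype=np.int64)])),
            "code": np.concatenate([bg_tok, fr_tok, np.array(fu_tok, dtype=object),
                                    np.array(sig_tok, dtype=object),
                                    np.array(dx_extra_tok, dtype=object)]),
        }
    )
    dx = dx.drop_duplicates(subset=["patient_id", "date", "code"])
    dx = dx.sort_values(["patient_id", "date", "code"], kind="mergesort").reset_index(drop=True)

    med = pd.DataFrame(
        {"patient_id": med_pid, "date": to_dates(med_off), "drug": med_drug}
    )
    med = med.drop_duplicates(subset=["patient_id", "date", "drug"])
    med = med.sort_values(["patient_id", "date", "drug"], kind="mergesort").reset_index(drop=True)

    demo = pd.DataFrame(
        {"patient_id": pids, "birth_date": to_dates(birth_off), "sex": sex}
    ).sort_values("patient_id", kind="mergesort").reset_index(drop=True)

    gt_frac = pd.DataFrame(
        {"patient_id": frac_pid, "date": to_dates(frac_off), "site": frac_site}
    ).sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)
    gt_iv = pd.DataFrame(
        iv_rows, columns=["patient_id", "offset", "kind", "name", "pharmacologic"]
    )
    if len(gt_iv):
        gt_iv["date"] = to_dates(gt_iv.pop("offset"))
    else:
        gt_iv = pd.DataFrame(columns=["patient_id", "kind", "name", "pharmacologic", "date"])
    gt_iv = gt_iv[["patient_id", "date", "kind", "name", "pharmacologic"]]
    gt_iv = gt_iv.sort_values(["patient_id", "date", "name"], kind="mergesort").reset_index(drop=True)

    return CohortData(dx, med, demo, GroundTruth(gt_frac, gt_iv), config)


def incidence_rate(
    anchors: list[AnchorEvent],
    birth_dates: dict[str, pd.Timestamp],
    min_age: float = 50.0,
) -> float:
    """Qualifying fracture events as a proportion of all anchor events
    among patients at least ``min_age`` at the event.  Patients can
    contribute several fracture anchors.  Raises if no anchor qualifies."""
    n_anchor = 0
    n_frac = 0
    for a in anchors:
        birth = birth_dates.get(a.patient_id)
        if birth is None or pd.isna(birth):
            continue
        if (a.date - birth).days / DAYS_PER_YEAR < min_age:
            continue
        n_anchor += 1
        n_frac += a.kind == "fracture"
    if n_anchor == 0:
        raise ValueError("no anchor events at or above the minimum age")
    return n_frac / n_anchor


def measured_incidence(
    cohort: CohortData,
    min_age: float = 50.0,
    washout_days: int = 90,
    catalog: FractureCatalog | None = None,
) -> tuple[float, int, int]:
    """Run fracture qualification + anchor detection on a generated cohort
    and return ``(incidence, n_fracture_anchors, n_anchors)``.

    Equivalent to assembling every record and calling the per-record
    qualifier, but only patients carrying fracture-coded rows go through
    the chronological scan; fracture-free patients anchor at their last
    diagnosis date directly.
    """
    catalog = catalog or FractureCatalog.default()
    dx = cohort.diagnoses
    if len(dx) == 0:
        raise ValueError("empty cohort")
    codes = dx["code"]
    mask = np.zeros(len(dx), dtype=bool)
    for pattern, _site in catalog.entries:
        mask |= codes.str.startswith(pattern).to_numpy()
    frac_rows = dx[mask]

    birth = dict(zip(cohort.demographics["patient_id"], cohort.demographics["birth_date"]))
    sexes = dict(zip(cohort.demographics["patient_id"], cohort.demographics["sex"]))

    anchors: list[AnchorEvent] = []
    frac_patients = set(frac_rows["patient_id"])
    for pid, g in frac_rows.groupby("patient_id", sort=True):
        rec = PatientRecord(
            patient_id=pid,
            birth_date=birth.get(pid),
            sex=sexes.get(pid, "unknown"),
            diagnoses=g[["date", "code"]].reset_index(drop=True),
            medications=pd.DataFrame({"date": [], "drug": []}),
        )
        evs = qualify_fracture_events(rec, washout_days, catalog)
        if evs:
            anchors.extend(AnchorEvent(pid, e.date, "fracture", e) for e in evs)
        else:
            frac_patients.discard(pid)

    last_dx = dx.groupby("patient_id", sort=True)["date"].max()
    for pid, d in last_dx.items():
        if pid not in frac_patients:
            anchors.append(AnchorEvent(pid, d, "last_diagnosis"))

    rate = incidence_rate(anchors, birth, min_age=min_age)
    n_elig = sum(
        1 for a in anchors
        if a.patient_id in birth
        and (a.date - birth[a.patient_id]).days / DAYS_PER_YEAR >= min_age
    )
    n_frac = sum(
        1 for a in anchors
        if a.kind == "fracture"
        and a.patient_id in birth
        and (a.date - birth[a.patient_id]).days / DAYS_PER_YEAR >= min_age
    )
    return rate, n_frac, n_elig


def null_config(**overrides) -> GeneratorConfig:
    """A label-independent cohort: no signal codes, no age effect, no
    frailty — codes are exchangeable between classes, so any model should
    score at chance."""
    base = dict(signal_codes={}, age_coeff=0.0, sex_coeff=0.0, frailty_sd=0.0,
                intervention_rate=0.0)
    base.update(overrides)
    return GeneratorConfig(**base)
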