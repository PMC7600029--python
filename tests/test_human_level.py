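import numpy as np
import pandas as pd
import pytest

from crystalbone.data_model import PatientRecord
from crystalbone.human_level import (
    CohortAnalysisReport,
    InterventionCatalog,
    OverlapAnalysisReport,
    cohort_analysis,
    detect_interventions,
    overlap_analysis,
)
from tests.test_fractures import make_record
from tests.test_windows import toy_window


@pytest.fixture(scope="module")
def catalog():
    return InterventionCatalog.default()


def record_with_meds(codes_by_day, meds_by_day, pid="p1"):
    rec = make_record(codes_by_day, patient_id=pid)
    med = pd.DataFrame(meds_by_day, columns=["date", "drug"])
    med["date"] = pd.to_datetime(med["date"])
    rec.medications = med.sort_values(["date", "drug"]).reset_index(drop=True)
    return rec


class TestCatalogMatching:
    def test_bisphosphonate_medication_is_pharmacologic_hit(self, catalog):
        rec = record_with_meds(
            [("2015-01-01", "SYN:C0001")], [("2015-06-01", "alendronate")]
        )
        win = toy_window("p1", False, end="2015-12-31")
        hit, entries = detect_interventions(rec, win, catalog)
        assert hit
        assert all(e.pharmacologic for e in entries)

    def test_drug_matching_is_case_insensitive_prefix(self, catalog):
        assert catalog.match_drug("Alendronate")
        assert catalog.match_drug("alendronate-cholecalciferol")
        assert catalog.match_drug("ZOLEDRONIC ACID")
        assert not catalog.match_drug("metformin")

    def test_densitometry_procedure_token_is_nonpharmacologic_hit(self, catalog):
        rec = make_record([("2015-06-01", "CPT:77080"), ("2015-01-01", "SYN:C0001")])
        win = toy_window("p1", False, end="2015-12-31")
        hit, entries = detect_interventions(rec, win, catalog)
        assert hit
        assert entries and not entries[0].pharmacologic

    def test_osteoporosis_diagnosis_stems_match_child_codes(self, catalog):
        for tok in ("ICD10:M80.08", "ICD10:M81.0", "ICD9:733.01"):
            assert catalog.match_code(tok), tok
        assert not catalog.match_code("ICD10:M84.48")

    def test_window_with_no_catalog_matches(self, catalog):
        rec = make_record([("2015-06-01", "SYN:C0001")])
        win = toy_window("p1", False, end="2015-12-31")
        assert detect_interventions(rec, win, catalog) == (False, [])

    def test_intervention_on_anchor_day_is_outside_window(self, catalog):
        # window_end = 2015-12-31; a DXA the day after (the anchor day)
        # must not count
        rec = make_record([("2016-01-01", "CPT:77080"), ("2015-01-01", "SYN:C0001")])
        win = toy_window("p1", False, end="2015-12-31")
        hit, _ = detect_interventions(rec, win, catalog)
        assert not hit

    def test_matching_equals_brute_force_scan(self, catalog, rng):
        tokens = ["SYN:C0001", "ICD10:M80.1", "CPT:77080", "ICD10:E11.9", "ICD9:733.00"]
        for trial in range(20):
            picks = list(rng.choice(tokens, size=4))
            rows = [(f"2015-0{i+1}-15", t) for i, t in enumerate(picks)]
            rec = make_record(rows)
            win = toy_window("p1", False, end="2015-12-31")
            hit, _ = detect_interventions(rec, win, catalog)
            brute = any(
                t.startswith(("ICD10:M80", "ICD10:M81", "ICD9:733.0", "CPT:"))
                for t in picks
            )
            assert hit == brute


class TestCohortAnalysisReport:
    def test_percentages_recompute_from_counts_to_one_decimal(self):
        rep = CohortAnalysisReport.from_counts(
            1000, 563, 5000, 860, 120, 101, 480, 162,
            unique_events_total=700, unique_events_flagged=491,
        )
        assert rep.flag_pct("no_intervention", "fracture") == 56.3
        assert rep.no_flag_pct("no_intervention", "fracture") == 43.7
        assert rep.flag_pct("no_intervention", "nonfracture") == 17.2
        assert rep.unique_event_flag_pct == 70.1
        assert rep.total_windows == 6600

    def test_flagged_count_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            CohortAnalysisReport.from_counts(10, 11, 0, 0, 0, 0, 0, 0)

    def test_partition_property_on_synthetic_windows(self, catalog, rng):
        records = {}
        wins = []
        for i in range(30):
            pid = f"p{i}"
            codes = [("2015-03-01", "SYN:C0001")]
            if i % 5 == 0:
                codes.append(("2015-06-01", "CPT:77080"))
            records[pid] = make_record(codes, patient_id=pid)
            wins.append(toy_window(pid, label=i % 3 == 0, end="2015-12-31"))
        flags = rng.random(30) < 0.5
        rep = cohort_analysis(wins, flags, records, catalog)
        assert rep.total_windows == 30
        assert sum(c["flag"] + c["no_flag"] for c in rep.cells.values()) == 30
        assert rep.cohort_total("intervention") == 6

    def test_all_flagged_degenerate_threshold(self, catalog):
        records = {"p0": make_record([("2015-03-01", "SYN:C0001")], patient_id="p0")}
        wins = [toy_window("p0", True, end="2015-12-31")]
        rep = cohort_analysis(wins, [True], records, catalog)
        assert all(c["no_flag"] == 0 for c in rep.cells.values())


class TestOverlapAnalysis:
    def _cohort(self):
        records = {}
        fractures = {}
        # p1: treated with 3 years of history, fractures after treatment
        records["p1"] = record_with_meds(
            [(f"2013-0{m}-01", "SYN:C0001") for m in range(1, 8)]
            + [("2012-01-01", "SYN:C0002"), ("2015-06-01", "SYN:C0003")],
            [("2015-07-01", "alendronate")],
            pid="p1",
        )
        from crystalbone.fractures import FractureEvent

        fractures["p1"] = [
            FractureEvent("p1", pd.Timestamp("2016-06-01"), "hip", False, "ICD10:S72.001A")
        ]
        # p2: treated but only ~1 year of prior history -> excluded
        records["p2"] = record_with_meds(
            [("2015-01-01", "SYN:C0001")], [("2015-12-01", "denosumab")], pid="p2"
        )
        fractures["p2"] = []
        # p3: never treated
        records["p3"] = record_with_meds(
            [("2014-01-01", "SYN:C0001")], [("2015-12-01", "metformin")], pid="p3"
        )
        fractures["p3"] = []
        return records, fractures

    def test_insufficient_history_counted_and_excluded(self, catalog):
        records, fractures = self._cohort()
        rep = overlap_analysis(records, fractures, lambda ws: [0.9] * len(ws), catalog)
        assert rep.n_treated == 2
        assert rep.n_sufficient_history == 1
        assert rep.n_flagged == 1
        assert rep.n_flagged_fractured == 1  # p1 fractures within 2 years

    def test_percentages_recompute_from_counts(self):
        rep = OverlapAnalysisReport(
            n_treated=7127,
            n_sufficient_history=6071,
            n_flagged=3017,
            n_flagged_fractured=684,
            n_fractured_total=570,
            n_fractured_flagged=469,
        )
        assert rep.flag_pct == 49.7
        assert rep.flagged_fracture_pct == 22.7
        assert rep.fractured_flag_pct == 82.3

    def test_non_nesting_counts_rejected(self):
        with pytest.raises(ValueError):
            OverlapAnalysisReport(10, 20, 5, 1, 2, 1)

    def test_interventions_precede_fractures_in_generator(self, small_cohort):
        """The generator injects most interventions ahead of fractures, so
        treated-and-fracturing patients have treatment before the event."""
        iv = small_cohort.ground_truth.interventions
        gt = small_cohort.ground_truth.fractures
        first_frac = gt.groupby("patient_id")["date"].min()
        pharm = iv[iv["pharmacologic"].astype(bool)]
        both = pharm[pharm["patient_id"].isin(first_frac.index)]
        assert len(both) > 0
        before = [
            row.date < first_frac[row.patient_id] for row in both.itertuples(index=False)
        ]
        assert np.mean(before) > 0.8
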