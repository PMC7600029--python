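from collections import Counter

import numpy as np
import pandas as pd
import pytest

from crystalbone.data_model import PatientRecord
from crystalbone.fractures import AnchorEvent, FractureEvent
from crystalbone.windows import (
    Window,
    build_all_windows,
    build_vocabulary,
    build_windows,
    oversample_balance,
    select_cohort,
    split_train_holdout,
)

EMPTY_MED = pd.DataFrame({"date": pd.Series(dtype="datetime64[ns]"), "drug": []})


def daily_record(pid, first_day, last_day, birth, step=30):
    days = pd.date_range(first_day, last_day, freq=f"{step}D")
    df = pd.DataFrame({"date": days, "code": [f"SYN:C{i % 7:04d}" for i in range(len(days))]})
    return PatientRecord(pid, pd.Timestamp(birth), "female", df, EMPTY_MED)


def fracture_anchor(pid, day):
    ev = FractureEvent(pid, pd.Timestamp(day), "hip", False, "ICD10:S72.001A")
    return AnchorEvent(pid, pd.Timestamp(day), "fracture", ev), ev


class TestSelectCohort:
    def _setup(self, age_years, history_days):
        anchor_day = pd.Timestamp("2016-01-01")
        birth = anchor_day - pd.Timedelta(days=int(np.ceil(age_years * 365.25)))
        rec = daily_record(
            "p1", anchor_day - pd.Timedelta(days=history_days), anchor_day, birth
        )
        anchor = AnchorEvent("p1", anchor_day, "last_diagnosis")
        return select_cohort({"p1": rec}, {"p1": [anchor]})

    def test_under_age_excluded_with_reason(self):
        sel = self._setup(49.9, 1000)
        assert sel.eligible == []
        assert sel.exclusions == {"under_age": 1}

    def test_age_50_with_731_days_history_included(self):
        sel = self._setup(50.0, 731)
        assert len(sel.eligible) == 1

    def test_insufficient_history_excluded(self):
        sel = self._setup(60.0, 500)
        assert sel.exclusions == {"insufficient_history": 1}

    def test_eligibility_matches_brute_force_on_simulated_anchors(
        self, small_records, small_anchors, small_selection
    ):
        expected = 0
        for pid, anchors in small_anchors.items():
            rec = small_records[pid]
            for a in anchors:
                age = (a.date - rec.birth_date).days / 365.25
                hist = (a.date - rec.diagnoses["date"].iloc[0]).days
                expected += age >= 50 and hist >= 730
        assert len(small_selection.eligible) == expected


class TestBuildWindows:
    def test_full_history_fracture_anchor_five_windows_with_horizon_labels(self):
        anchor, ev = fracture_anchor("p1", "2016-01-01")
        rec = daily_record("p1", "2011-06-01", "2016-01-01", "1945-01-01", step=20)
        wins = build_windows(anchor, rec, [ev])
        assert len(wins) == 5
        gaps = [w.time_to_event for w in wins]
        assert gaps == [1, 184, 367, 550, 733]
        assert [w.label for w in wins] == [True, True, True, True, False]

    def test_minimal_history_yields_single_window(self):
        anchor, ev = fracture_anchor("p1", "2016-01-01")
        first = pd.Timestamp("2016-01-01") - pd.Timedelta(days=731)
        rec = daily_record("p1", first, "2015-12-31", "1945-01-01", step=20)
        wins = build_windows(anchor, rec, [ev])
        assert len(wins) == 1
        assert wins[0].time_to_event == 1

    def test_nonfracture_anchor_windows_all_negative(self):
        rec = daily_record("p1", "2011-06-01", "2016-01-01", "1945-01-01", step=20)
        anchor = AnchorEvent("p1", pd.Timestamp("2016-01-01"), "last_diagnosis")
        wins = build_windows(anchor, rec, [])
        assert len(wins) == 5
        assert not any(w.label for w in wins)

    def test_other_fracture_in_horizon_drops_candidate(self):
        anchor, ev = fracture_anchor("p1", "2016-01-01")
        other = FractureEvent("p1", pd.Timestamp("2015-06-01"), "wrist/forearm",
                              False, "ICD10:S52.501A")
        rec = daily_record("p1", "2011-06-01", "2016-01-01", "1945-01-01", step=20)
        wins = build_windows(anchor, rec, [ev, other])
        # every candidate whose span or horizon contains the other fracture
        # is dropped
        for w in wins:
            start = w.window_end - pd.Timedelta(days=730)
            horizon_end = w.window_end + pd.Timedelta(days=730)
            assert not (start < other.date <= horizon_end)

    def test_anchor_day_codes_never_leak_into_window(self):
        anchor, ev = fracture_anchor("p1", "2016-01-01")
        rec = daily_record("p1", "2011-06-01", "2016-01-01", "1945-01-01", step=20)
        wins = build_windows(anchor, rec, [ev])
        for w in wins:
            assert all(d <= w.window_end for d in
                       rec.diagnoses.loc[rec.diagnoses["code"].isin(w.codes), "date"].iloc[:1])
            assert w.window_end < anchor.date

    def test_labels_match_ground_truth_brute_force(self, small_cohort, small_windows):
        gt = small_cohort.ground_truth.fractures
        by_pid = {pid: list(g["date"]) for pid, g in gt.groupby("patient_id")}
        for w in small_windows:
            expected = any(
                w.window_end < d <= w.window_end + pd.Timedelta(days=730)
                for d in by_pid.get(w.patient_id, [])
            )
            assert w.label == expected

    def test_window_ends_unique_and_capped_per_anchor(self, small_windows):
        ends = Counter((w.patient_id, w.window_end) for w in small_windows)
        assert max(ends.values()) == 1
        per_anchor = Counter((w.patient_id, w.anchor.date) for w in small_windows)
        assert max(per_anchor.values()) <= 5

    def test_no_window_crosses_first_diagnosis(self, small_records, small_windows):
        for w in small_windows:
            first = small_records[w.patient_id].first_dx_date
            assert first <= w.window_end - pd.Timedelta(days=730)


def toy_window(pid, label, codes=("SYN:C0001",), end="2015-06-01", sex="female",
               age=70.0, source="natural", tag="pan_therapeutic"):
    anchor = AnchorEvent(pid, pd.Timestamp(end) + pd.Timedelta(days=1),
                         "fracture" if label else "last_diagnosis")
    return Window(
        patient_id=pid, anchor=anchor, window_end=pd.Timestamp(end),
        codes=list(codes), label=label, time_to_event=1, age=age, sex=sex,
        dx_count=len(codes), cohort_tag=tag, source=source,
    )


class TestVocabulary:
    def test_min_count_boundary(self):
        wins = [toy_window("p1", False, ["A:x"] * 4 + ["A:y"] * 5)]
        vocab = build_vocabulary(wins, min_count=5)
        assert "A:y" in vocab
        assert "A:x" not in vocab

    def test_counts_match_brute_force_counter(self, rng):
        tokens = [f"A:t{i}" for i in range(10)]
        wins = [
            toy_window(f"p{j}", False, list(rng.choice(tokens, size=30)))
            for j in range(5)
        ]
        vocab = build_vocabulary(wins, min_count=1)
        brute = Counter(c for w in wins for c in w.codes)
        assert vocab.counts == dict(brute)

    def test_index_order_deterministic_frequency_then_lexicographic(self):
        wins = [toy_window("p1", False, ["A:b"] * 3 + ["A:a"] * 3 + ["A:c"] * 5)]
        vocab = build_vocabulary(wins, min_count=1)
        assert vocab.tokens[2:] == ["A:c", "A:a", "A:b"]

    def test_empty_corpus_is_an_error(self):
        with pytest.raises(ValueError):
            build_vocabulary([toy_window("p1", False, [])])


class TestSplit:
    def test_ten_patients_split_seven_three(self):
        wins = [toy_window(f"p{i}", False) for i in range(10)]
        plan = split_train_holdout(wins, 0.7, seed=1)
        assert len(plan.train_patients) == 7
        assert len(plan.holdout_patients) == 3

    def test_same_seed_identical_plan(self):
        wins = [toy_window(f"p{i}", False) for i in range(25)]
        assert split_train_holdout(wins, 0.7, 3) == split_train_holdout(wins, 0.7, 3)

    def test_patient_disjointness_over_many_plans(self, rng):
        wins = [toy_window(f"p{i % 17}", bool(i % 5 == 0)) for i in range(60)]
        for seed in range(50):
            plan = split_train_holdout(wins, 0.7, seed)
            assert not (plan.train_patients & plan.holdout_patients)
            assert plan.train_patients | plan.holdout_patients == {
                f"p{i}" for i in range(17)
            }


class TestOversample:
    def _pool(self, n):
        return [toy_window(f"b{i}", True, tag="bone_health") for i in range(n)]

    def test_already_balanced_is_noop(self):
        wins = [toy_window(f"p{i}", i < 5) for i in range(10)]
        assert len(oversample_balance(wins, self._pool(3), 0)) == 10

    def test_deficit_arithmetic(self):
        wins = [toy_window(f"p{i}", i < 10) for i in range(100)]  # 10 pos, 90 neg
        out = oversample_balance(wins, self._pool(200), 0)
        assert len(out) == 180
        added = [w for w in out if w.source == "oversampled"]
        assert len(added) == 80

    def test_balance_property_with_small_pool_resampling(self, rng):
        for trial in range(10):
            n_pos = int(rng.integers(1, 20))
            n_neg = int(rng.integers(n_pos, 80))
            wins = [toy_window(f"p{i}", i < n_pos) for i in range(n_pos + n_neg)]
            out = oversample_balance(wins, self._pool(5), seed=trial)
            pos = sum(w.label for w in out)
            assert pos == len(out) - pos

    def test_empty_pool_with_imbalance_is_an_error(self):
        wins = [toy_window(f"p{i}", i < 2) for i in range(10)]
        with pytest.raises(ValueError):
            oversample_balance(wins, [], 0)

    def test_pool_with_negative_windows_rejected(self):
        wins = [toy_window(f"p{i}", i < 2) for i in range(10)]
        with pytest.raises(ValueError):
            oversample_balance(wins, [toy_window("b1", False)], 0)
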