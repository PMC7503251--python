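"""Event-log model, I/O, case building and preprocessing remedies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_log, random_log
from erppi import (
    ColumnMap,
    EventLog,
    LogValidationError,
    aggregate,
    deduplicate_collateral,
    infer_start_times,
    read_csv_log,
    read_xes_log,
    rebuild_cases,
    remove_imperfect_cases,
    write_csv_log,
    write_xes_log,
)

H = 3600


def ts(hhmm, day=0):  # minutes-resolution timestamps on an arbitrary day
    h, m = hhmm.split(":")
    return day * 86400 + int(h) * 3600 + int(m) * 60 + 1_500_000_000


class TestReadCsv:
    def test_snippet_structure(self, snippet_log):
        assert len(snippet_log) == 2
        assert sum(len(c.events) for c in snippet_log.cases) == 5
        assert snippet_log.activity_alphabet == {"Entry", "Treatment",
                                                 "Consultation"}
        case1 = snippet_log.cases[0]
        assert case1.patient_id == "P1"
        assert case1.emergency == 3
        assert case1.variant() == ("Entry", "Treatment", "Consultation")

    def test_dayfirst_dialect(self, snippet_log):
        # 01/02/2018 is the 1st of February under the day-first dialect
        import pandas as pd

        first = pd.Timestamp(snippet_log.cases[0].events[0].timestamp, unit="s")
        assert (first.day, first.month, first.year) == (1, 2, 2018)
        assert (first.hour, first.minute) == (19, 5)

    def test_header_only_file(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("CaseID,Activity,Timestamp\n")
        assert len(read_csv_log(p)) == 0

    def test_identical_timestamps_keep_input_order(self, tmp_path):
        p = tmp_path / "tie.csv"
        p.write_text(
            "CaseID,Activity,Timestamp\n"
            "1,B,2018-02-01T19:05:00\n"
            "1,A,2018-02-01T19:05:00\n"
        )
        log = read_csv_log(p)
        assert len(log) == 1
        assert [e.activity for e in log.cases[0].events] == ["B", "A"]

    def test_missing_mandatory_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("CaseID,Activity\n1,Entry\n")
        with pytest.raises(LogValidationError, match="Timestamp"):
            read_csv_log(p)

    def test_unparseable_timestamp_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("CaseID,Activity,Timestamp\n1,Entry,not-a-time\n")
        with pytest.raises(LogValidationError, match="row 2"):
            read_csv_log(p)

    def test_emergency_out_of_range(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("CaseID,Activity,Timestamp,Emergency\n"
                     "1,Entry,2018-02-01T19:05:00,9\n")
        with pytest.raises(LogValidationError, match="emergency"):
            read_csv_log(p)
        log = read_csv_log(p, coerce_emergency=True)
        assert log.cases[0].emergency is None


class TestRoundTrips:
    def test_csv_round_trip(self, snippet_log, tmp_path):
        out = tmp_path / "out.csv"
        write_csv_log(snippet_log, out)
        back = read_csv_log(out)
        self._assert_logs_equal(snippet_log, back)

    def test_xes_round_trip(self, snippet_log, tmp_path):
        out = tmp_path / "out.xes"
        write_xes_log(snippet_log, out)
        back = read_xes_log(out)
        self._assert_logs_equal(snippet_log, back)

    def test_xes_trace_without_events_rejected(self, tmp_path):
        p = tmp_path / "bad.xes"
        p.write_text('<log><trace><string key="concept:name" value="c"/>'
                     "</trace></log>")
        with pytest.raises(LogValidationError, match="trace 0"):
            read_xes_log(p)

    @staticmethod
    def _assert_logs_equal(a: EventLog, b: EventLog):
        assert len(a) == len(b)
        for ca, cb in zip(a.cases, b.cases):
            assert (ca.case_id, ca.patient_id, ca.emergency) == \
                   (cb.case_id, cb.patient_id, cb.emergency)
            for ea, eb in zip(ca.events, cb.events):
                assert (ea.activity, ea.timestamp, ea.event_type,
                        ea.originator, ea.cost) == \
                       (eb.activity, eb.timestamp, eb.event_type,
                        eb.originator, eb.cost)


class TestRebuildCases:
    def test_visit_gap_partition(self):
        log = make_log([("x", [("entry", ts("09:00")), ("test", ts("09:30")),
                               ("entry", ts("10:00", day=1))], "P1")])
        out = rebuild_cases(log, "patient_visit", visit_gap=6 * H)
        assert len(out) == 2
        assert [len(c.events) for c in out.cases] == [2, 1]
        assert all(c.patient_id == "P1" for c in out.cases)

    def test_single_event(self):
        log = make_log([("x", [("entry", ts("09:00"))], "P1")])
        assert len(rebuild_cases(log, "patient_visit")) == 1

    def test_interleaved_patients_never_mix(self):
        rng = np.random.default_rng(7)
        log = random_log(rng, max_cases=30)
        out = rebuild_cases(log, "patient_visit", visit_gap=H)
        for case in out.cases:
            assert case.case_id.startswith(case.patient_id)

    def test_requires_patient_id(self):
        log = make_log([("x", [("entry", ts("09:00"))])])
        with pytest.raises(LogValidationError, match="patient_id"):
            rebuild_cases(log, "patient_visit")

    def test_given_case_id_passthrough(self, snippet_log):
        assert rebuild_cases(snippet_log, "given_case_id") is snippet_log


class TestRemoveImperfectCases:
    def test_time_travel_removed(self):
        log = make_log([
            ("bad", [("diagnostic test", ts("18:00")), ("entry", ts("19:00"))]),
            ("good", [("entry", ts("19:00")), ("test", ts("19:30"))]),
        ])
        clean, removed = remove_imperfect_cases(log)
        assert [c.case_id for c in clean.cases] == ["good"]
        assert [(r.case_id, r.pattern) for r in removed] == \
               [("bad", "time_travel")]

    def test_clean_snippet_passes_through(self, snippet_log):
        clean, removed = remove_imperfect_cases(snippet_log, "Entry")
        assert removed == []
        assert len(clean) == 2

    @pytest.mark.parametrize("threshold,expect_removed", [(2, True),
                                                          (3, True),
                                                          (4, False)])
    def test_form_based_threshold_boundary(self, threshold, expect_removed):
        t = ts("19:10")
        log = make_log([("c", [("entry", ts("19:00")), ("a", t), ("b", t),
                               ("c", t)])])
        clean, removed = remove_imperfect_cases(log, form_threshold=threshold)
        assert (len(removed) == 1) is expect_removed
        if expect_removed:
            assert removed[0].pattern == "form_based"

    def test_conservation_and_idempotence(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            log = random_log(rng)
            clean, removed = remove_imperfect_cases(log)
            assert len(clean) + len(removed) == len(log)
            again, removed2 = remove_imperfect_cases(clean)
            assert removed2 == []
            assert len(again) == len(clean)


class TestDeduplicate:
    def test_duplicate_collapsed(self):
        t = ts("19:17")
        log = make_log([("c", [("entry", ts("19:05"), "complete", "John"),
                               ("treatment", t, "complete", "Jane"),
                               ("treatment", t, "complete", "Jane")])])
        out, n = deduplicate_collateral(log)
        assert n == 1
        assert len(out.cases[0].events) == 2

    def test_no_duplicates(self, snippet_log):
        out, n = deduplicate_collateral(snippet_log)
        assert n == 0

    def test_three_copies_keep_one(self):
        t = ts("19:17")
        log = make_log([("c", [("treatment", t)] * 3)])
        out, n = deduplicate_collateral(log)
        assert n == 2 and len(out.cases[0].events) == 1
        again, n2 = deduplicate_collateral(out)
        assert n2 == 0


class TestInferStartTimes:
    def test_snippet_inference_rule(self, snippet_log):
        ivs = infer_start_times(snippet_log.cases[0])
        # first event: zero duration; Treatment starts when Entry completed
        assert ivs[0].duration == 0
        assert ivs[1].start == ivs[0].complete
        assert ivs[1].duration == 12 * 60

    def test_explicit_pair_keeps_interval(self):
        log = make_log([("c", [("entry", ts("19:00")),
                               ("scan", ts("19:20"), "start"),
                               ("scan", ts("19:35"), "complete")])])
        ivs = infer_start_times(log.cases[0])
        assert [iv.event.activity for iv in ivs] == ["entry", "scan"]
        assert (ivs[1].start, ivs[1].complete) == (ts("19:20"), ts("19:35"))

    def test_no_negative_durations(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            log = random_log(rng)
            for c in log.cases:
                assert all(iv.duration >= 0 for iv in infer_start_times(c))


class TestAggregate:
    @pytest.mark.parametrize("f,expected", [
        ("avg", 2.5), ("med", 2.5), ("min", 1.0), ("max", 4.0),
        ("std", 1.118033988749895),
    ])
    def test_named_functions(self, f, expected):
        assert aggregate([1, 2, 3, 4], f) == pytest.approx(expected)

    def test_single_value_median(self):
        assert aggregate([5], "med") == 5

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="no measurements"):
            aggregate([], "avg")

    def test_sample_std_option(self):
        assert aggregate([1, 3], "std", std_ddof=1) == pytest.approx(
            np.std([1, 3], ddof=1))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.sampled_from("abc"),
                          st.integers(0, 100)), min_size=1, max_size=8))
def test_case_events_always_sorted(pairs):
    """Case construction sorts events by timestamp, stably."""
    log = make_log([("c", [(a, 1_500_000_000 + t) for a, t in pairs])])
    stamps = [e.timestamp for e in log.cases[0].events]
    assert stamps == sorted(stamps)
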