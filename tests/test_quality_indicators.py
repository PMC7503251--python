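"""Quality-perspective indicators: LOS variation, workload, stochastic
matching rate, triage accuracy, response rate, revisit rate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import levenshtein_dp, transport_optimum
from conftest import make_case, make_log, random_log
from erppi import (
    EventLog,
    StochasticLanguage,
    TimeGrid,
    VitalFeatures,
    default_rule_table,
    log_language,
    los_std,
    matching_rate,
    normalized_levenshtein,
    revisit_rate,
    triage_accuracy,
    triage_response_rate,
    workload,
)

H = 3600
T0 = 1_500_000_000


class TestLosStd:
    def test_identical_stays_have_zero_spread(self):
        log = make_log([("a", [("x", T0), ("y", T0 + H)]),
                        ("b", [("x", T0 + 9), ("y", T0 + 9 + H)])])
        assert los_std(log) == 0.0

    def test_two_stays_population_std(self):
        log = make_log([("a", [("x", T0), ("y", T0 + H)]),
                        ("b", [("x", T0), ("y", T0 + 3 * H)])])
        assert los_std(log) == pytest.approx(H)  # {1 h, 3 h} -> 1 h

    def test_requires_two_cases(self):
        log = make_log([("a", [("x", T0)])])
        with pytest.raises(ValueError):
            los_std(log)


class TestWorkload:
    def test_cross_bin_event_leaves_one_open(self):
        # one event starting in bin 1, completing in bin 2 -> series (1, 0)
        log = make_log([("c", [("a", T0 + 100, "complete", "doc"),
                               ("b", T0 + H + 100, "complete", "doc")])])
        grid = TimeGrid(origin=T0, width=H, n_bins=2)
        series = workload(log, "doc", grid)
        assert series.values.tolist() == [1, 0]

    def test_within_bin_event_nets_zero(self):
        log = make_log([("c", [("a", T0 + 100, "complete", "doc"),
                               ("b", T0 + 200, "complete", "doc")])])
        grid = TimeGrid(origin=T0, width=H, n_bins=3)
        assert workload(log, "doc", grid).values.tolist() == [0, 0, 0]

    def test_recursion_and_telescoping_identities(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            log = random_log(rng)
            grid = TimeGrid.covering(log)
            resources = {e.originator for e in log.iter_events()
                         if e.originator}
            for r in resources:
                s = workload(log, r, grid)
                v = s.values
                assert v[0] == s.started[0] - s.completed[0]
                for j in range(1, len(v)):
                    assert v[j] == v[j - 1] + s.started[j] - s.completed[j]
                assert v[-1] == s.started.sum() - s.completed.sum()

    def test_unknown_resource(self, snippet_log):
        with pytest.raises(ValueError, match="known"):
            workload(snippet_log, "nobody")


class TestStochasticLanguage:
    def test_snippet_language(self, snippet_log):
        lang = log_language(snippet_log)
        assert lang.entries == {
            ("Entry", "Treatment", "Consultation"): 0.5,
            ("Entry", "Treatment"): 0.5,
        }

    def test_single_case_log(self):
        log = make_log([("c", [("a", T0)])])
        assert log_language(log).entries == {("a",): 1.0}

    def test_invalid_sum_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            StochasticLanguage({("a",): 0.4, ("b",): 0.4})

    def test_csv_round_trip(self, tmp_path):
        lang = StochasticLanguage({("a", "b"): 0.25, ("c",): 0.75})
        path = tmp_path / "lang.csv"
        lang.to_csv(path)
        assert StochasticLanguage.from_csv(path).entries == lang.entries


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from("abcd"), max_size=6),
       st.lists(st.sampled_from("abcd"), max_size=6))
def test_normalized_levenshtein_matches_dp(a, b):
    expected = 0.0 if not a and not b else \
        levenshtein_dp(a, b) / max(len(a), len(b))
    assert normalized_levenshtein(a, b) == pytest.approx(expected)


class TestMatchingRate:
    def test_identical_languages_match_perfectly(self):
        lang = StochasticLanguage({("a", "b"): 0.5, ("c",): 0.5})
        assert matching_rate(lang, lang) == pytest.approx(1.0, abs=1e-12)

    def test_single_substitution_halves_the_rate(self):
        a = StochasticLanguage({("a", "b"): 1.0})
        b = StochasticLanguage({("a", "c"): 1.0})
        assert matching_rate(a, b) == pytest.approx(0.5, abs=1e-12)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            x = _random_language(rng)
            y = _random_language(rng)
            mxy = matching_rate(x, y)
            assert 0.0 <= mxy <= 1.0 + 1e-12
            assert mxy == pytest.approx(matching_rate(y, x), abs=1e-9)

    def test_equals_bruteforce_transport_optimum(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            x = _random_language(rng)
            y = _random_language(rng)
            cost = [[normalized_levenshtein(v, w) for w in y.entries]
                    for v in x.entries]
            expected = 1.0 - transport_optimum(
                list(x.entries.values()), list(y.entries.values()), cost)
            assert matching_rate(x, y) == pytest.approx(expected, abs=1e-9)


def _random_language(rng, max_variants=4):
    n = int(rng.integers(1, max_variants + 1))
    variants = set()
    while len(variants) < n:
        length = int(rng.integers(1, 5))
        variants.add(tuple(rng.choice(["a", "b", "c", "d"], size=length)))
    p = rng.dirichlet(np.ones(len(variants)))
    return StochasticLanguage(dict(zip(sorted(variants), p)))


class TestTriageAccuracy:
    def _log_with_vitals(self, levels):
        table = default_rule_table()
        cases = []
        for i, lvl in enumerate(levels):
            c = make_case(f"c{i}", [("entry", T0 + i)], patient_id=f"p{i}",
                          emergency=lvl)
            # vitals that the default table classifies as exactly lvl
            from erppi.simulate import _sample_vitals_for_level

            c.attrs["vitals"] = _sample_vitals_for_level(
                np.random.default_rng(i), lvl, table)
            cases.append(c)
        return EventLog(cases=cases), table

    def test_consistent_classifier_scores_one(self):
        log, table = self._log_with_vitals([1, 2, 3, 4, 5, 3, 2])
        result = triage_accuracy(log, table.classify)
        assert result.accuracy == 1.0
        assert result.n_evaluated == 7

    def test_constant_classifier_on_half_level3_log(self):
        log, _ = self._log_with_vitals([3, 1, 3, 2, 3, 4, 3, 5])
        result = triage_accuracy(log, lambda v: 3)
        assert result.accuracy == 0.5

    def test_accuracy_equals_confusion_trace(self):
        log, table = self._log_with_vitals([1, 1, 2, 5, 4, 3])
        result = triage_accuracy(log, lambda v: 5)
        assert result.accuracy == pytest.approx(
            np.trace(result.confusion) / result.confusion.sum())

    def test_cases_without_vitals_excluded(self):
        log, table = self._log_with_vitals([2, 3])
        bare = make_case("bare", [("entry", T0)], emergency=1)
        log = EventLog(cases=log.cases + [bare])
        result = triage_accuracy(log, table.classify)
        assert result.n_evaluated == 2 and result.n_excluded == 1

    def test_rule_table_json_round_trip(self, tmp_path):
        from erppi import TriageRuleTable

        table = default_rule_table()
        path = tmp_path / "rules.json"
        table.to_json(path)
        back = TriageRuleTable.from_json(path)
        vit = VitalFeatures(gcs=7, spo2=99, pain=0)
        assert back.classify(vit) == table.classify(vit) == 1


class TestTriageResponseRate:
    def test_snippet_has_no_violation(self, snippet_log):
        rates = triage_response_rate(snippet_log)
        assert list(rates.values()) == [1.0]

    def test_equal_urgency_never_violates(self):
        log = _served_log(ktas=[3] * 6, swap=None)
        assert list(triage_response_rate(log).values()) == [1.0]

    def test_single_swap_costs_one_over_n_minus_one(self):
        n = 8
        fcfs = triage_response_rate(_served_log(ktas=[3] * n, swap=None))
        swapped = triage_response_rate(
            _served_log(ktas=[5, 1] + [3] * (n - 2), swap=(0, 1)))
        assert list(fcfs.values()) == [1.0]
        assert list(swapped.values()) == [pytest.approx(1.0 - 1 / (n - 1))]

    def test_direction_flag_flips_the_penalty(self):
        log = _served_log(ktas=[1, 5, 3, 3], swap=(0, 1))
        printed = triage_response_rate(log)
        flipped = triage_response_rate(log, direction="urgency_first")
        assert list(printed.values()) == [1.0]
        assert list(flipped.values()) == [pytest.approx(1.0 - 1 / 3)]

    def test_invariant_under_time_translation(self):
        log = _served_log(ktas=[4, 2, 3, 1, 5], swap=(2, 3))
        shifted = _served_log(ktas=[4, 2, 3, 1, 5], swap=(2, 3), shift=7 * H)
        assert list(triage_response_rate(log).values()) == \
               list(triage_response_rate(shifted).values())


def _served_log(ktas, swap, shift=0):
    """Cases arriving 10 min apart, second event 5 min later (FCFS order);
    optionally swap the second-event times of two adjacent cases."""
    t2 = [T0 + shift + 600 * k + 300 for k in range(len(ktas))]
    if swap is not None:
        i, j = swap
        t2[i], t2[j] = t2[j], t2[i]
    cases = []
    for k, lvl in enumerate(ktas):
        cases.append((f"c{k}", [("entry", T0 + shift + 600 * k),
                                ("treat", t2[k])], f"p{k}", lvl))
    return make_log(cases)


class TestRevisitRate:
    def test_distinct_patients_never_revisit(self, snippet_log):
        assert revisit_rate(snippet_log) == 0.0

    def test_single_returning_patient(self):
        log = make_log([
            ("v1", [("entry", T0), ("out", T0 + H)], "p1"),
            ("v2", [("entry", T0 + 3 * H), ("out", T0 + 4 * H)], "p1"),
        ])
        assert revisit_rate(log, 24 * H) == 1.0

    def test_window_boundary_is_inclusive(self):
        log = make_log([
            ("v1", [("entry", T0), ("out", T0 + H)], "p1"),
            ("v2", [("entry", T0 + H + 24 * H), ("out", T0 + 26 * H)], "p1"),
        ])
        assert revisit_rate(log, 24 * H) == 1.0
        assert revisit_rate(log, 24 * H - 1) == 0.0

    def test_start_to_start_mode(self):
        log = make_log([
            ("v1", [("entry", T0), ("out", T0 + 10 * H)], "p1"),
            ("v2", [("entry", T0 + 12 * H), ("out", T0 + 13 * H)], "p1"),
        ])
        assert revisit_rate(log, 11 * H) == 1.0  # end-to-start gap 2 h
        assert revisit_rate(log, 11 * H, mode="start_to_start") == 0.0

    def test_invariant_under_time_translation(self):
        rng = np.random.default_rng(41)
        log = random_log(rng)
        shifted = EventLog(cases=[
            make_case(c.case_id,
                      [(e.activity, e.timestamp + 12345) for e in c.events],
                      c.patient_id, c.emergency)
            for c in log.cases
        ])
        assert revisit_rate(log) == revisit_rate(shifted)
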