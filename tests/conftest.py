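import numpy as np
import pytest

from erppi import Case, Event, EventLog

# Clinical-extract snippet used across tests: two cases, five events, one
# start-typed consultation with no matching complete.
SNIPPET_CSV = """\
CaseID,Activity,Timestamp,Type,Resource,Emergency,PatientID
1,Entry,01/02/2018 19:05,Complete,John,3,P1
1,Treatment,01/02/2018 19:17,Complete,Jane,3,P1
1,Consultation,01/02/2018 19:20,Start,Tom,3,P1
2,Entry,01/02/2018 19:21,Complete,John,1,P2
2,Treatment,01/02/2018 19:36,Complete,Jane,1,P2
"""


@pytest.fixture
def snippet_path(tmp_path):
    path = tmp_path / "snippet.csv"
    path.write_text(SNIPPET_CSV)
    return path


@pytest.fixture
def snippet_log(snippet_path):
    from erppi import read_csv_log

    return read_csv_log(snippet_path)


def make_case(case_id, events, patient_id=None, emergency=None):
    """events: iterable of (activity, ts) or (activity, ts, type, resource)."""
    evs = []
    for spec in events:
        activity, ts = spec[0], spec[1]
        etype = spec[2] if len(spec) > 2 else "complete"
        resource = spec[3] if len(spec) > 3 else None
        cost = spec[4] if len(spec) > 4 else None
        evs.append(Event(activity=activity, timestamp=int(ts),
                         event_type=etype, originator=resource, cost=cost))
    return Case(case_id=case_id, events=evs, patient_id=patient_id,
                emergency=emergency)


def make_log(case_specs):
    return EventLog(cases=[make_case(*spec) for spec in case_specs])


def random_log(rng: np.random.Generator, max_cases=50, alphabet=None,
               with_resources=True, with_emergency=True) -> EventLog:
    """Arbitrary structurally-valid complete-only log for property tests."""
    alphabet = alphabet or ["entry", "triage", "test", "consult", "discharge"]
    n_cases = int(rng.integers(1, max_cases + 1))
    cases = []
    for k in range(n_cases):
        n_events = int(rng.integers(1, 9))
        ts = int(rng.integers(1_500_000_000, 1_500_500_000))
        events = []
        for _ in range(n_events):
            events.append(Event(
                activity=str(rng.choice(alphabet)),
                timestamp=ts,
                originator=f"r{int(rng.integers(4))}" if with_resources else None,
            ))
            ts += int(rng.integers(1, 7200))
        cases.append(Case(
            case_id=f"c{k}", events=events,
            patient_id=f"p{int(rng.integers(max(2, n_cases // 2)))}",
            emergency=int(rng.integers(1, 6)) if with_emergency else None,
        ))
    return EventLog(cases=cases)
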