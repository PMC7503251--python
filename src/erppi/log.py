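"""Event-log data model, I/O and preprocessing for ER process analysis.

The in-memory model follows the standard process-mining view of a clinical
event log: a log is a multiset of traces, each trace the ordered event
sequence of one case (one patient episode).  Events carry an activity, an
optional originator (the clinician recorded as performing the event), a
timestamp, a lifecycle type (``start``/``complete``) and an optional cost.
Cases additionally carry a patient identifier and a triage acuity value
(KTAS level 1-5, lower = more urgent).

Besides reading/writing CSV and XES, this module implements the standard
remedies for the event-log data-imperfection patterns seen in emergency
department extracts:

* *exclusive case* -- patient identifiers reused as case identifiers break
  down for same-day revisits; :func:`rebuild_cases` re-partitions events
  into visits by a time gap.
* *inadvertent time travel* -- events timestamped before the ER arrival;
  the affected case is deleted (:func:`remove_imperfect_cases`).
* *form-based event capture* -- many distinct activities saved at one
  identical instant when a form is submitted; the case is deleted.
* *collateral events* -- exact duplicate rows; all but the first copy are
  dropped (:func:`deduplicate_collateral`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from lxml import etree

logger = logging.getLogger("erppi")

# ---------------------------------------------------------------------------
# Module-wide configuration constants
# ---------------------------------------------------------------------------

#: lifecycle transition alphabet
EVENT_TYPES = ("start", "complete")
#: valid triage acuity levels (KTAS); lower value = more urgent
EMERGENCY_LEVELS = (1, 2, 3, 4, 5)
#: default activity label marking ER arrival
DEFAULT_ENTRY_LABEL = "entry"
#: default activity label marking the physician consultation
DEFAULT_CONSULTATION_LABEL = "consultation"
#: default number of distinct activities at one instant that marks
#: form-based event capture
DEFAULT_FORM_THRESHOLD = 3
#: default visit gap (seconds) separating two ER visits of one patient
DEFAULT_VISIT_GAP = 24 * 3600
#: default timestamp format of day-first clinical CSV extracts
DEFAULT_TIMESTAMP_DIALECT = "%d/%m/%Y %H:%M"
#: timestamp format used when writing CSV (second resolution, ISO 8601,
#: auto-detected on read)
ISO_WRITE_FORMAT = "%Y-%m-%dT%H:%M:%S"

SEVERE, MODERATE, MILD = frozenset({1, 2}), frozenset({3}), frozenset({4, 5})
#: named KTAS groupings used throughout reporting
EMERGENCY_GROUPS: dict[str, frozenset[int]] = {
    "severe": SEVERE,
    "moderate": MODERATE,
    "mild": MILD,
}


class LogValidationError(ValueError):
    """Raised when an input log violates the data contract."""


def norm_label(label: str) -> str:
    """Normalise an activity/resource label for comparison (trim + casefold)."""
    return label.strip().casefold()


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class Event:
    """One recorded event: an activity performed at an instant.

    ``timestamp`` is timezone-naive seconds since the Unix epoch.
    """

    activity: str
    timestamp: int
    event_type: str = "complete"
    originator: str | None = None
    cost: float | None = None
    attrs: dict | None = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise LogValidationError(
                f"event_type must be one of {EVENT_TYPES}, got {self.event_type!r}"
            )
        if self.cost is not None and self.cost < 0:
            raise LogValidationError(f"cost must be >= 0, got {self.cost}")


@dataclass(slots=True)
class Case:
    """One patient episode: an ordered trace of events.

    Events are kept sorted by timestamp; ties preserve input order
    (stable sort), since clinical extracts define no secondary key.
    """

    case_id: str
    events: list[Event]
    patient_id: str | None = None
    emergency: int | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.events:
            raise LogValidationError(f"case {self.case_id!r} has no events")
        if self.emergency is not None and self.emergency not in EMERGENCY_LEVELS:
            raise LogValidationError(
                f"case {self.case_id!r}: emergency {self.emergency!r} not in 1..5"
            )
        self.events = sorted(self.events, key=lambda e: e.timestamp)

    # -- projections ------------------------------------------------------

    def effective_events(self) -> list[Event]:
        """Events that represent performed work, in order.

        ``complete`` events always count.  A ``start`` event whose activity
        has a later matching ``complete`` in the same case is lifecycle
        metadata (the pair is one interval and the ``complete`` event stands
        for it); a start event with no matching complete is promoted to an
        instantaneous event, because the log recorded only the initiation.
        """
        completes_left: dict[str, int] = {}
        for e in self.events:
            if e.event_type == "complete":
                key = norm_label(e.activity)
                completes_left[key] = completes_left.get(key, 0) + 1
        out: list[Event] = []
        seen_completes: dict[str, int] = {}
        for e in self.events:
            key = norm_label(e.activity)
            if e.event_type == "complete":
                seen_completes[key] = seen_completes.get(key, 0) + 1
                out.append(e)
            else:  # start: paired iff a complete of same activity lies ahead
                remaining = completes_left.get(key, 0) - seen_completes.get(key, 0)
                if remaining <= 0:
                    out.append(e)
        return out

    def variant(self) -> tuple[str, ...]:
        """Ordered activity sequence of the case (its trace variant)."""
        return tuple(e.activity for e in self.effective_events())

    @property
    def start_time(self) -> int:
        return self.events[0].timestamp

    @property
    def end_time(self) -> int:
        return self.events[-1].timestamp


@dataclass
class EventLog:
    """A multiset of traces grouped into cases."""

    cases: list[Case]

    def __post_init__(self) -> None:
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise LogValidationError(f"duplicate case_ids: {sorted(dupes)[:5]}")
        # canonical spelling per normalised label: first occurrence wins
        self._canon: dict[str, str] = {}
        for e in self.iter_events():
            self._canon.setdefault(norm_label(e.activity), e.activity)

    def __len__(self) -> int:
        return len(self.cases)

    def iter_events(self) -> Iterator[Event]:
        for c in self.cases:
            yield from c.events

    @property
    def activity_alphabet(self) -> set[str]:
        return set(self._canon.values())

    @property
    def span(self) -> tuple[int, int]:
        """(earliest, latest) timestamp over all events."""
        ts = [e.timestamp for e in self.iter_events()]
        return (min(ts), max(ts))

    def canonical_label(self, label: str) -> str | None:
        """Return the log's spelling of *label*, or None if absent."""
        return self._canon.get(norm_label(label))

    def require_activity(self, label: str) -> str:
        canon = self.canonical_label(label)
        if canon is None:
            known = sorted(self.activity_alphabet)
            raise LogValidationError(
                f"activity {label!r} not in log; known activities: {known}"
            )
        return canon


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from CSV column headers to log fields.

    Defaults follow the usual clinical-extract headers
    (CaseID, Activity, Timestamp, Type, Resource, Emergency, PatientID, Cost).
    """

    case_id: str = "CaseID"
    activity: str = "Activity"
    timestamp: str = "Timestamp"
    event_type: str | None = "Type"
    resource: str | None = "Resource"
    emergency: str | None = "Emergency"
    patient_id: str | None = "PatientID"
    cost: str | None = "Cost"
    timestamp_dialect: str = DEFAULT_TIMESTAMP_DIALECT


# ---------------------------------------------------------------------------
# CSV / XES I/O
# ---------------------------------------------------------------------------


def _parse_timestamps(raw: pd.Series, dialect: str) -> pd.Series:
    """Parse a timestamp column: ISO 8601 auto-detected, else the dialect.

    Raises :class:`LogValidationError` naming the first offending data row.
    """
    try:
        parsed = pd.to_datetime(raw, format="ISO8601")
        return parsed
    except (ValueError, TypeError):
        pass
    parsed = pd.to_datetime(raw, format=dialect, errors="coerce")
    if parsed.isna().any():
        bad = parsed.index[parsed.isna()][0]
        raise LogValidationError(
            f"row {bad + 2}: unparseable timestamp {raw.loc[bad]!r} "
            f"(expected ISO 8601 or {dialect!r})"
        )
    return parsed


def _coerce_emergency(value, *, coerce: bool, row: int) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        level = int(float(value))
    except (TypeError, ValueError):
        level = -1
    if level not in EMERGENCY_LEVELS:
        if coerce:
            return None
        raise LogValidationError(
            f"row {row}: emergency value {value!r} outside 1..5"
        )
    return level


def read_csv_log(
    path: str | Path,
    colmap: ColumnMap | None = None,
    *,
    coerce_emergency: bool = False,
) -> EventLog:
    """Read a clinical event log from CSV.

    One event per row, grouped into cases by the case-id column; events are
    sorted per case by timestamp with stable tie order.  Missing optional
    columns simply leave the corresponding fields absent.
    """
    colmap = colmap or ColumnMap()
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for mandatory in (colmap.case_id, colmap.activity, colmap.timestamp):
        if mandatory not in df.columns:
            raise LogValidationError(
                f"{path.name}: mandatory column {mandatory!r} missing "
                f"(have {list(df.columns)})"
            )
    if df.empty:
        return EventLog(cases=[])

    ts = _parse_timestamps(df[colmap.timestamp], colmap.timestamp_dialect)
    epoch = (ts.astype("int64") // 10**9).to_numpy()

    def optcol(name: str | None) -> list | None:
        return df[name].tolist() if name and name in df.columns else None

    types = optcol(colmap.event_type)
    resources = optcol(colmap.resource)
    emergencies = optcol(colmap.emergency)
    patients = optcol(colmap.patient_id)
    costs = optcol(colmap.cost)
    mapped = {
        colmap.case_id, colmap.activity, colmap.timestamp, colmap.event_type,
        colmap.resource, colmap.emergency, colmap.patient_id, colmap.cost,
    }
    extra_cols = [c for c in df.columns if c not in mapped]

    grouped: dict[str, Case] = {}
    for i, (cid, act) in enumerate(zip(df[colmap.case_id], df[colmap.activity])):
        etype = "complete"
        if types is not None and types[i].strip():
            etype = types[i].strip().casefold()
            if etype not in EVENT_TYPES:
                raise LogValidationError(
                    f"row {i + 2}: event type {types[i]!r} not in {EVENT_TYPES}"
                )
        cost = None
        if costs is not None and costs[i].strip():
            cost = float(costs[i])
        attrs = {c: df[c].iloc[i] for c in extra_cols if df[c].iloc[i] != ""} or None
        event = Event(
            activity=act,
            timestamp=int(epoch[i]),
            event_type=etype,
            originator=(resources[i] or None) if resources is not None else None,
            cost=cost,
            attrs=attrs,
        )
        if cid not in grouped:
            emer = (
                _coerce_emergency(emergencies[i], coerce=coerce_emergency, row=i + 2)
                if emergencies is not None
                else None
            )
            pid = (patients[i] or None) if patients is not None else None
            grouped[cid] = Case(case_id=cid, events=[event], patient_id=pid,
                                emergency=emer)
        else:
            grouped[cid].events.append(event)
    # re-sort (Case sorted only at construction)
    cases = [
        Case(c.case_id, c.events, c.patient_id, c.emergency, c.attrs)
        for c in grouped.values()
    ]
    log = EventLog(cases=cases)
    logger.info("read_csv_log path=%s cases=%d events=%d", path.name, len(log),
                sum(len(c.events) for c in log.cases))
    return log


def write_csv_log(log: EventLog, path: str | Path,
                  colmap: ColumnMap | None = None) -> None:
    """Write a log to CSV with second-resolution ISO timestamps.

    ``read_csv_log(write_csv_log(L))`` reproduces ``L`` field-for-field for
    all mapped fields.
    """
    colmap = colmap or ColumnMap()
    rows = []
    for case in log.cases:
        for e in case.events:
            rows.append({
                colmap.case_id: case.case_id,
                colmap.activity: e.activity,
                colmap.timestamp: pd.Timestamp(e.timestamp, unit="s")
                .strftime(ISO_WRITE_FORMAT),
                colmap.event_type or "Type": e.event_type,
                colmap.resource or "Resource": e.originator or "",
                colmap.emergency or "Emergency":
                    case.emergency if case.emergency is not None else "",
                colmap.patient_id or "PatientID": case.patient_id or "",
                colmap.cost or "Cost": "" if e.cost is None else e.cost,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


_XES_NS = "http://www.xes-standard.org/"


def write_xes_log(log: EventLog, path: str | Path) -> None:
    """Write the log as a basic XES document."""
    root = etree.Element("log")
    for case in log.cases:
        tr = etree.SubElement(root, "trace")
        etree.SubElement(tr, "string", key="concept:name", value=case.case_id)
        if case.patient_id is not None:
            etree.SubElement(tr, "string", key="patient:id", value=case.patient_id)
        if case.emergency is not None:
            etree.SubElement(tr, "int", key="emergency", value=str(case.emergency))
        for e in case.events:
            ev = etree.SubElement(tr, "event")
            etree.SubElement(ev, "string", key="concept:name", value=e.activity)
            etree.SubElement(
                ev, "date", key="time:timestamp",
                value=pd.Timestamp(e.timestamp, unit="s").isoformat(),
            )
            etree.SubElement(ev, "string", key="lifecycle:transition",
                             value=e.event_type)
            if e.originator is not None:
                etree.SubElement(ev, "string", key="org:resource",
                                 value=e.originator)
            if e.cost is not None:
                etree.SubElement(ev, "float", key="cost", value=str(e.cost))
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")


def read_xes_log(path: str | Path) -> EventLog:
    """Read a basic XES document (concept:name / time:timestamp /
    lifecycle:transition / org:resource keys)."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise LogValidationError(f"malformed XES: {exc}") from exc
    root = tree.getroot()

    def strip(tag: str) -> str:
        return tag.split("}", 1)[-1]

    def kv(elem) -> dict[str, str]:
        return {ch.get("key"): ch.get("value") for ch in elem
                if strip(ch.tag) in {"string", "int", "float", "date"}}

    cases: list[Case] = []
    for idx, tr in enumerate(el for el in root if strip(el.tag) == "trace"):
        tattrs = kv(tr)
        events: list[Event] = []
        for ev in (el for el in tr if strip(el.tag) == "event"):
            a = kv(ev)
            if "concept:name" not in a or "time:timestamp" not in a:
                raise LogValidationError(
                    f"trace {idx}: event missing concept:name/time:timestamp"
                )
            events.append(Event(
                activity=a["concept:name"],
                timestamp=int(pd.Timestamp(a["time:timestamp"]).value // 10**9),
                event_type=a.get("lifecycle:transition", "complete").casefold(),
                originator=a.get("org:resource"),
                cost=float(a["cost"]) if "cost" in a else None,
            ))
        if not events:
            raise LogValidationError(f"trace {idx}: no events")
        cases.append(Case(
            case_id=tattrs.get("concept:name", f"trace_{idx}"),
            events=events,
            patient_id=tattrs.get("patient:id"),
            emergency=int(tattrs["emergency"]) if "emergency" in tattrs else None,
        ))
    return EventLog(cases=cases)


# ---------------------------------------------------------------------------
# Case (re)construction -- the "exclusive case" remedy
# ---------------------------------------------------------------------------


def rebuild_cases(
    log: EventLog,
    strategy: str = "patient_visit",
    visit_gap: int = DEFAULT_VISIT_GAP,
) -> EventLog:
    """Re-partition events into cases.

    ``given_case_id`` keeps the existing partition.  ``patient_visit``
    implements the remedy for the *exclusive case* imperfection: all events
    of one patient are pooled and split into visits wherever consecutive
    events are separated by more than ``visit_gap`` seconds; the new case id
    is ``<patient_id>@<first event ISO timestamp>``.
    """
    if strategy == "given_case_id":
        return log
    if strategy != "patient_visit":
        raise ValueError(f"unknown strategy {strategy!r}")
    pools: dict[str, list[tuple[Event, int | None]]] = {}
    order: list[str] = []
    for case in log.cases:
        if case.patient_id is None:
            raise LogValidationError(
                f"case {case.case_id!r} has no patient_id; "
                "patient_visit strategy requires one"
            )
        pools.setdefault(case.patient_id, [])
        if case.patient_id not in order:
            order.append(case.patient_id)
        for e in case.events:
            pools[case.patient_id].append((e, case.emergency))
    cases: list[Case] = []
    for pid in order:
        pool = sorted(pools[pid], key=lambda pair: pair[0].timestamp)
        visit: list[tuple[Event, int | None]] = []
        for pair in pool:
            if visit and pair[0].timestamp - visit[-1][0].timestamp > visit_gap:
                cases.append(_visit_case(pid, visit))
                visit = []
            visit.append(pair)
        if visit:
            cases.append(_visit_case(pid, visit))
    return EventLog(cases=cases)


def _visit_case(pid: str, visit: list[tuple[Event, int | None]]) -> Case:
    first_ts = pd.Timestamp(visit[0][0].timestamp, unit="s").strftime(ISO_WRITE_FORMAT)
    emer = next((em for _, em in visit if em is not None), None)
    return Case(
        case_id=f"{pid}@{first_ts}",
        events=[e for e, _ in visit],
        patient_id=pid,
        emergency=emer,
    )


# ---------------------------------------------------------------------------
# Imperfection remedies: deletion-based
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RemovalRecord:
    case_id: str
    pattern: str  # "time_travel" | "form_based"


def remove_imperfect_cases(
    log: EventLog,
    entry_activity: str = DEFAULT_ENTRY_LABEL,
    form_threshold: int = DEFAULT_FORM_THRESHOLD,
) -> tuple[EventLog, list[RemovalRecord]]:
    """Delete cases showing time-travel or form-based capture patterns.

    *time_travel*: some event is timestamped strictly before the case's
    first entry-labelled event.  *form_based*: at least ``form_threshold``
    distinct activities share one identical timestamp.  Whole-case deletion
    is the remedy; the report lists each removed case with the first pattern
    matched (time_travel takes precedence).
    """
    entry_norm = norm_label(entry_activity)
    kept: list[Case] = []
    removed: list[RemovalRecord] = []
    for case in log.cases:
        pattern = None
        entry_ts = next((e.timestamp for e in case.events
                         if norm_label(e.activity) == entry_norm), None)
        if entry_ts is not None and any(e.timestamp < entry_ts for e in case.events):
            pattern = "time_travel"
        if pattern is None:
            by_ts: dict[int, set[str]] = {}
            for e in case.events:
                by_ts.setdefault(e.timestamp, set()).add(norm_label(e.activity))
            if any(len(acts) >= form_threshold for acts in by_ts.values()):
                pattern = "form_based"
        if pattern is None:
            kept.append(case)
        else:
            removed.append(RemovalRecord(case.case_id, pattern))
    logger.info("remove_imperfect_cases kept=%d removed=%d", len(kept), len(removed))
    return EventLog(cases=kept), removed


def deduplicate_collateral(log: EventLog) -> tuple[EventLog, int]:
    """Collapse within-case events identical on
    (activity, timestamp, event_type, originator), keeping the first copy."""
    n_removed = 0
    cases: list[Case] = []
    for case in log.cases:
        seen: set[tuple] = set()
        events: list[Event] = []
        for e in case.events:
            key = (norm_label(e.activity), e.timestamp, e.event_type, e.originator)
            if key in seen:
                n_removed += 1
            else:
                seen.add(key)
                events.append(e)
        cases.append(Case(case.case_id, events, case.patient_id,
                          case.emergency, case.attrs))
    return EventLog(cases=cases), n_removed


def preprocess(
    log: EventLog,
    entry_activity: str = DEFAULT_ENTRY_LABEL,
    form_threshold: int = DEFAULT_FORM_THRESHOLD,
) -> tuple[EventLog, dict]:
    """Standard preprocessing pipeline: deduplicate collateral events, then
    delete time-travel / form-based cases.  Returns the clean log and a
    summary dict (removal records + duplicate count)."""
    deduped, n_dupes = deduplicate_collateral(log)
    clean, removed = remove_imperfect_cases(deduped, entry_activity, form_threshold)
    summary = {
        "duplicates_removed": n_dupes,
        "cases_removed": [{"case_id": r.case_id, "pattern": r.pattern}
                          for r in removed],
        "cases_in": len(log),
        "cases_out": len(clean),
    }
    return clean, summary


# ---------------------------------------------------------------------------
# Start-time inference (interval view)
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class Interval:
    """Resolved (start, complete) instants for one effective event."""

    event: Event
    start: int
    complete: int

    @property
    def duration(self) -> int:
        return self.complete - self.start


def infer_start_times(case: Case) -> list[Interval]:
    """Interval view of a case.

    For a complete-only trace the start of event *i* (i>1) is the complete
    time of event *i-1*; the first event has zero duration.  An explicit
    ``start`` event paired with a later ``complete`` of the same activity
    keeps its recorded interval; unpaired start events are instantaneous.
    """
    # map each effective complete event to an explicit start partner, if any
    pending: dict[str, list[int]] = {}
    explicit: dict[int, int] = {}  # id(event) -> start ts
    for e in case.events:
        key = norm_label(e.activity)
        if e.event_type == "start":
            pending.setdefault(key, []).append(e.timestamp)
        elif pending.get(key):
            explicit[id(e)] = pending[key].pop(0)
    out: list[Interval] = []
    prev_complete: int | None = None
    for e in case.effective_events():
        if id(e) in explicit:
            start = explicit[id(e)]
        elif prev_complete is None:
            start = e.timestamp
        else:
            start = prev_complete
        out.append(Interval(event=e, start=start, complete=e.timestamp))
        prev_complete = e.timestamp
    return out


def log_intervals(log: EventLog) -> dict[str, list[Interval]]:
    """Interval view for every case, keyed by case id."""
    return {c.case_id: infer_start_times(c) for c in log.cases}


# ---------------------------------------------------------------------------
# Aggregation functions
# ---------------------------------------------------------------------------

AGGREGATORS = ("avg", "med", "min", "max", "std")


def aggregate(values: Sequence[float], f: str, *, std_ddof: int = 0) -> float:
    """Apply a named aggregation function (AVG, MED, MIN, MAX, STD).

    STD is the population standard deviation by default (``std_ddof=0``);
    pass ``std_ddof=1`` for the sample version.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no measurements")
    f = f.casefold()
    if f == "avg":
        return float(arr.mean())
    if f == "med":
        return float(np.median(arr))
    if f == "min":
        return float(arr.min())
    if f == "max":
        return float(arr.max())
    if f == "std":
        return float(arr.std(ddof=std_ddof))
    raise ValueError(f"unknown aggregation {f!r}; choose from {AGGREGATORS}")
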