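"""Time-perspective performance indicators for ER event logs.

Six indicators: length of stay (overall, by variant, by triage acuity),
cycle time of a clinical activity, initial response time after arrival,
and Door-To-Doctor time.  Each returns per-case/per-occurrence duration
samples in seconds; :func:`summarize` reduces a sample list to the
standard AVG/MED/MIN/MAX block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .log import (
    DEFAULT_CONSULTATION_LABEL,
    DEFAULT_ENTRY_LABEL,
    EMERGENCY_GROUPS,
    Case,
    EventLog,
    aggregate,
    norm_label,
)

SECONDS_PER_HOUR = 3600.0
SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True, slots=True)
class DurationSample:
    """One measured duration (seconds) with its case of origin."""

    case_id: str
    value: float
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"negative duration for case {self.case_id}")


VariantSelector = Callable[[tuple[str, ...]], bool]


def los(log: EventLog) -> list[DurationSample]:
    """Length of stay per case: last minus first effective-event timestamp."""
    out = []
    for c in log.cases:
        eff = c.effective_events()
        out.append(DurationSample(c.case_id, float(eff[-1].timestamp - eff[0].timestamp)))
    return out


def los_by_variant(
    log: EventLog,
    selector: tuple[str, ...] | VariantSelector,
) -> list[DurationSample]:
    """LOS restricted to cases whose variant satisfies *selector*.

    *selector* is either an exact variant (activity tuple, matched after
    label normalisation) or a predicate over the variant.  A selector that
    matches no case yields an empty list.
    """
    if callable(selector):
        pred = selector
    else:
        target = tuple(norm_label(a) for a in selector)

        def pred(v: tuple[str, ...]) -> bool:
            return tuple(norm_label(a) for a in v) == target

    samples = []
    for c, s in zip(log.cases, los(log)):
        if pred(c.variant()):
            samples.append(s)
    return samples


def terminal_selector(terminal_activity: str) -> VariantSelector:
    """Selector for cases ending in a given activity (e.g. the
    hospitalized-vs-discharged split)."""
    t = norm_label(terminal_activity)
    return lambda v: bool(v) and norm_label(v[-1]) == t


def los_by_emergency(
    log: EventLog, levels: Iterable[int] | str
) -> tuple[list[DurationSample], int]:
    """LOS restricted to cases with triage acuity in *levels*.

    *levels* may be a set of KTAS values or one of the named presets
    ``severe`` ({1,2}), ``moderate`` ({3}), ``mild`` ({4,5}).  Returns the
    samples and the number of cases excluded for lacking an acuity value.
    """
    if isinstance(levels, str):
        try:
            level_set = EMERGENCY_GROUPS[levels.casefold()]
        except KeyError:
            raise ValueError(
                f"unknown preset {levels!r}; choose from {sorted(EMERGENCY_GROUPS)}"
            ) from None
    else:
        level_set = frozenset(levels)
    if not level_set:
        raise ValueError("levels must be a non-empty subset of 1..5")
    if not level_set <= {1, 2, 3, 4, 5}:
        raise ValueError(f"levels {sorted(level_set)} outside 1..5")
    samples, n_unlabelled = [], 0
    for c, s in zip(log.cases, los(log)):
        if c.emergency is None:
            n_unlabelled += 1
        elif c.emergency in level_set:
            samples.append(s)
    return samples, n_unlabelled


def cycle_time(log: EventLog, activity: str) -> list[DurationSample]:
    """Cycle time of an activity: for every occurrence with a successor in
    its case, the gap to that successor.  Case-final occurrences yield no
    sample."""
    canon = log.require_activity(activity)
    target = norm_label(canon)
    samples = []
    for c in log.cases:
        eff = c.effective_events()
        for i in range(len(eff) - 1):
            if norm_label(eff[i].activity) == target:
                samples.append(DurationSample(
                    c.case_id,
                    float(eff[i + 1].timestamp - eff[i].timestamp),
                    {"successor": eff[i + 1].activity},
                ))
    return samples


def initial_response_time(
    log: EventLog, entry_label: str = DEFAULT_ENTRY_LABEL
) -> tuple[list[DurationSample], int]:
    """Time from ER arrival to its immediate successor event.

    Uses the first entry-labelled event per case.  Cases without an entry
    event, or whose entry is the last event, are skipped and counted.
    """
    target = norm_label(entry_label)
    samples, skipped = [], 0
    for c in log.cases:
        eff = c.effective_events()
        idx = next((i for i, e in enumerate(eff)
                    if norm_label(e.activity) == target), None)
        if idx is None or idx == len(eff) - 1:
            skipped += 1
            continue
        samples.append(DurationSample(
            c.case_id, float(eff[idx + 1].timestamp - eff[idx].timestamp)
        ))
    return samples, skipped


def door_to_doctor_time(
    log: EventLog,
    entry_label: str = DEFAULT_ENTRY_LABEL,
    consultation_label: str = DEFAULT_CONSULTATION_LABEL,
    consultation_occurrence: str = "first",
) -> tuple[list[DurationSample], int]:
    """Per case: first consultation timestamp minus first entry timestamp.

    ``consultation_occurrence`` may be ``first`` (Door-To-Doctor semantics,
    default) or ``last``.  Cases lacking either activity are skipped and
    counted; so are cases whose only consultations precede the arrival
    (a time-travel pattern that preprocessing normally deletes).
    """
    if consultation_occurrence not in ("first", "last"):
        raise ValueError("consultation_occurrence must be 'first' or 'last'")
    t_entry, t_cons = norm_label(entry_label), norm_label(consultation_label)
    samples, skipped = [], 0
    for c in log.cases:
        eff = c.effective_events()
        entries = [e.timestamp for e in eff if norm_label(e.activity) == t_entry]
        cons = [e.timestamp for e in eff
                if norm_label(e.activity) == t_cons
                and (not entries or e.timestamp >= entries[0])]
        if not entries or not cons:
            skipped += 1
            continue
        chosen = cons[0] if consultation_occurrence == "first" else cons[-1]
        samples.append(DurationSample(c.case_id, float(chosen - entries[0])))
    return samples, skipped


def summarize(
    samples: Sequence[DurationSample],
    unit: str = "s",
    *,
    skipped: int = 0,
) -> dict:
    """Reduce duration samples to the standard aggregate block.

    ``unit`` converts seconds to ``s``, ``m`` (minutes) or ``h`` (hours).
    """
    scale = {"s": 1.0, "m": SECONDS_PER_MINUTE, "h": SECONDS_PER_HOUR}[unit]
    block: dict = {"n": len(samples), "unit": unit, "skipped": skipped}
    if samples:
        values = [s.value / scale for s in samples]
        for f in ("avg", "med", "min", "max"):
            block[f] = aggregate(values, f)
    return block
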