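"""Quality-perspective indicators.

Covers: variation of length of stay, per-resource workload over a time
grid, the stochastic matching rate between the log and a reference model
(an optimal-transport comparison of trace-variant distributions under a
normalized edit ground distance), triage accuracy against a rule-based
classifier, the triage-based patient response rate, and the patient
revisit rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Callable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .cost_indicators import TimeGrid
from .log import Case, EventLog, aggregate, log_intervals, norm_label
from .time_indicators import los, terminal_selector

PROB_TOL = 1e-9


# ---------------------------------------------------------------------------
# Variation of length of stay
# ---------------------------------------------------------------------------


def los_std(log: EventLog, *, ddof: int = 0,
            terminal_activity: str | None = None) -> float:
    """Standard deviation of the length of stay (population by default).

    With *terminal_activity*, restrict to cases ending in that activity
    (the hospitalized-vs-discharged comparison).
    """
    samples = los(log)
    if terminal_activity is not None:
        sel = terminal_selector(terminal_activity)
        samples = [s for c, s in zip(log.cases, samples) if sel(c.variant())]
    if len(samples) < 2:
        raise ValueError("need at least 2 cases to measure LOS variation")
    return aggregate([s.value for s in samples], "std", std_ddof=ddof)


# ---------------------------------------------------------------------------
# Workload of resources
# ---------------------------------------------------------------------------


@dataclass
class WorkloadSeries:
    """Running workload of one resource over a time grid.

    ``values[j]`` counts the resource's events started but not yet
    completed by the end of bin j: the per-bin difference of started and
    completed event counts, accumulated from the first bin.
    """

    resource: str
    grid: TimeGrid
    started: np.ndarray
    completed: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return np.cumsum(self.started - self.completed)


def workload(log: EventLog, resource: str, grid: TimeGrid | None = None
             ) -> WorkloadSeries:
    """Workload series of *resource*: per bin, events started minus events
    completed, cumulated.  Start instants come from the interval view
    (the preceding event's completion when only complete events exist)."""
    known = {e.originator for e in log.iter_events() if e.originator is not None}
    if resource not in known:
        raise ValueError(f"unknown resource {resource!r}; known: {sorted(known)}")
    grid = grid or TimeGrid.covering(log)
    started = np.zeros(grid.n_bins, dtype=int)
    completed = np.zeros(grid.n_bins, dtype=int)
    for ivs in log_intervals(log).values():
        for iv in ivs:
            if iv.event.originator != resource:
                continue
            b0, b1 = grid.bin_of(iv.start), grid.bin_of(iv.complete)
            if b0 is not None:
                started[b0] += 1
            if b1 is not None:
                completed[b1] += 1
    return WorkloadSeries(resource=resource, grid=grid,
                          started=started, completed=completed)


# ---------------------------------------------------------------------------
# Stochastic languages and the matching rate
# ---------------------------------------------------------------------------


@dataclass
class StochasticLanguage:
    """A probability distribution over trace variants."""

    entries: dict[tuple[str, ...], float]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.entries:
            raise ValueError("empty stochastic language")
        total = 0.0
        for variant, p in self.entries.items():
            if p < 0:
                raise ValueError(f"negative probability for variant {variant}")
            total += p
        if abs(total - 1.0) > PROB_TOL:
            raise ValueError(f"probabilities sum to {total!r}, not 1")

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = ">") -> "StochasticLanguage":
        """Read a language file: columns ``variant`` (activities joined by
        ``>``) and ``probability``."""
        df = pd.read_csv(path, dtype={"variant": str, "probability": float})
        entries = {
            tuple(a.strip() for a in row.variant.split(sep)): float(row.probability)
            for row in df.itertuples()
        }
        return cls(entries=entries)

    def to_csv(self, path: str | Path, sep: str = ">") -> None:
        rows = [{"variant": sep.join(v), "probability": p}
                for v, p in self.entries.items()]
        pd.DataFrame(rows).to_csv(path, index=False)


def log_language(log: EventLog) -> StochasticLanguage:
    """Empirical variant distribution of a log: case count / total cases."""
    if len(log) == 0:
        raise ValueError("empty log has no stochastic language")
    counts: dict[tuple[str, ...], int] = {}
    for c in log.cases:
        v = c.variant()
        counts[v] = counts.get(v, 0) + 1
    n = len(log)
    return StochasticLanguage({v: k / n for v, k in counts.items()})


def normalized_levenshtein(a: Sequence[str], b: Sequence[str]) -> float:
    """Levenshtein distance between two activity sequences divided by
    max(|a|, |b|); 0 for two empty sequences.  Bounded in [0, 1]."""
    if not a and not b:
        return 0.0
    alphabet: dict[str, str] = {}
    for label in (*a, *b):
        if label not in alphabet:
            alphabet[label] = chr(0x100 + len(alphabet))
    sa = "".join(alphabet[x] for x in a)
    sb = "".join(alphabet[x] for x in b)
    d = edlib.align(sa, sb, mode="NW", task="distance")["editDistance"]
    return d / max(len(a), len(b))


GroundDistance = Callable[[Sequence[str], Sequence[str]], float]


def matching_rate(
    log_lang: StochasticLanguage,
    model_lang: StochasticLanguage,
    distance: GroundDistance = normalized_levenshtein,
) -> float:
    """Stochastic conformance of a log against a reference model.

    Solves the transportation problem that optimally reallocates the log's
    variant probability mass onto the model's, with ground cost
    ``distance`` (normalized edit distance by default, so the result lies
    in [0, 1]); returns 1 minus the optimal transport cost.  The measure is
    symmetric in its two arguments and equals 1 iff the languages coincide.
    """
    log_lang.validate()
    model_lang.validate()
    src = list(log_lang.entries.items())
    dst = list(model_lang.entries.items())
    n, m = len(src), len(dst)
    cost = np.empty((n, m))
    for i, (v, _) in enumerate(src):
        for j, (w, _) in enumerate(dst):
            cost[i, j] = distance(v, w)
    supply = np.array([p for _, p in src])
    demand = np.array([p for _, p in dst])
    # equality-constrained transportation LP; one constraint is redundant
    a_eq = np.zeros((n + m, n * m))
    for i in range(n):
        a_eq[i, i * m:(i + 1) * m] = 1.0
    for j in range(m):
        a_eq[n + j, j::m] = 1.0
    res = linprog(
        cost.ravel(),
        A_eq=a_eq,
        b_eq=np.concatenate([supply, demand]),
        bounds=(0, None),
        method="highs",
        options={"primal_feasibility_tolerance": 1e-10,
                 "dual_feasibility_tolerance": 1e-10},
    )
    if not res.success:  # pragma: no cover - tiny feasible LPs always solve
        raise RuntimeError(f"transportation LP failed: {res.message}")
    return 1.0 - float(res.fun)


# ---------------------------------------------------------------------------
# Triage accuracy
# ---------------------------------------------------------------------------

VITAL_RANGES: dict[str, tuple[float, float]] = {
    "gcs": (3, 15),       # Glasgow Coma Scale
    "spo2": (0, 100),     # pulse oxygen saturation, %
    "sbp": (0, 300),      # systolic blood pressure, mmHg
    "pulse": (0, 300),    # beats per minute
    "resp": (0, 80),      # breaths per minute
    "temp": (25, 45),     # body temperature, deg C
    "pain": (0, 10),      # pain score
}


@dataclass(frozen=True, slots=True)
class VitalFeatures:
    """Vital signs recorded at triage.  Any field may be absent."""

    gcs: float | None = None
    spo2: float | None = None
    sbp: float | None = None
    pulse: float | None = None
    resp: float | None = None
    temp: float | None = None
    pain: float | None = None
    entry_type: str | None = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in VITAL_RANGES.items():
            v = getattr(self, name)
            if v is not None and not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


@dataclass(frozen=True, slots=True)
class TriageRule:
    """One threshold condition: feature OP bound."""

    feature: str
    op: str  # "<=", "<", ">=", ">"
    bound: float

    def holds(self, vitals: VitalFeatures) -> bool:
        v = getattr(vitals, self.feature)
        if v is None:
            return False
        if self.op == "<=":
            return v <= self.bound
        if self.op == "<":
            return v < self.bound
        if self.op == ">=":
            return v >= self.bound
        if self.op == ">":
            return v > self.bound
        raise ValueError(f"unknown operator {self.op!r}")


@dataclass
class TriageRuleTable:
    """Deterministic rule-based triage classifier.

    Levels are evaluated most-urgent-first (1, 2, 3, 4); the first level
    with any satisfied condition is assigned, else level 5.  The table
    shipped by :func:`default_rule_table` is a synthetic placeholder with
    clinically plausible thresholds, NOT any ministry's official table.
    """

    rules: dict[int, list[TriageRule]]

    def __post_init__(self) -> None:
        for level in self.rules:
            if level not in (1, 2, 3, 4):
                raise ValueError("rule levels must be 1..4 (5 is the default)")

    def classify(self, vitals: VitalFeatures) -> int:
        for level in (1, 2, 3, 4):
            if any(rule.holds(vitals) for rule in self.rules.get(level, [])):
                return level
        return 5

    @classmethod
    def from_json(cls, path: str | Path) -> "TriageRuleTable":
        data = json.loads(Path(path).read_text())
        rules = {
            int(level): [TriageRule(r["feature"], r["op"], float(r["bound"]))
                         for r in conds]
            for level, conds in data.items()
        }
        return cls(rules=rules)

    def to_json(self, path: str | Path) -> None:
        data = {
            str(level): [{"feature": r.feature, "op": r.op, "bound": r.bound}
                         for r in conds]
            for level, conds in self.rules.items()
        }
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))


def default_rule_table() -> TriageRuleTable:
    """Synthetic placeholder triage table (see :class:`TriageRuleTable`)."""
    return TriageRuleTable(rules={
        1: [TriageRule("gcs", "<=", 8), TriageRule("spo2", "<", 85),
            TriageRule("sbp", "<", 70)],
        2: [TriageRule("gcs", "<=", 12), TriageRule("spo2", "<", 90),
            TriageRule("pain", ">=", 8), TriageRule("pulse", ">", 130),
            TriageRule("resp", ">", 30), TriageRule("temp", ">=", 40)],
        3: [TriageRule("gcs", "<=", 14), TriageRule("spo2", "<", 94),
            TriageRule("pain", ">=", 4), TriageRule("pulse", ">", 110),
            TriageRule("resp", ">", 24), TriageRule("temp", ">=", 38.5),
            TriageRule("sbp", ">", 180)],
        4: [TriageRule("pain", ">=", 1), TriageRule("pulse", ">", 100),
            TriageRule("temp", ">=", 37.5)],
    })


@dataclass
class TriageAccuracy:
    """Accuracy of recorded acuity against the classifier, with the 5x5
    confusion table (rows = classifier level, cols = recorded level)."""

    accuracy: float
    confusion: np.ndarray
    n_evaluated: int
    n_excluded: int


def triage_accuracy(
    log: EventLog,
    classifier: Callable[[VitalFeatures], int],
    *,
    vitals_key: str = "vitals",
) -> TriageAccuracy:
    """Fraction of cases where the classifier's level equals the recorded
    acuity.  Cases missing vitals (``case.attrs[vitals_key]``) or a
    recorded acuity are excluded and counted."""
    confusion = np.zeros((5, 5), dtype=int)
    n_excluded = 0
    for c in log.cases:
        vit = c.attrs.get(vitals_key)
        if vit is None or c.emergency is None:
            n_excluded += 1
            continue
        predicted = classifier(vit)
        confusion[predicted - 1, c.emergency - 1] += 1
    n_eval = int(confusion.sum())
    if n_eval == 0:
        raise ValueError("no cases with both vitals and a recorded acuity")
    return TriageAccuracy(
        accuracy=float(np.trace(confusion)) / n_eval,
        confusion=confusion,
        n_evaluated=n_eval,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Triage-based patient response rate
# ---------------------------------------------------------------------------


def triage_response_rate(
    log: EventLog,
    grid: TimeGrid | None = None,
    *,
    direction: str = "printed",
) -> dict[int, float | None]:
    """Per-period fraction of adjacent case pairs served consistently with
    triage priority.

    Cases with an acuity value and at least two events are sorted by their
    first event time; consecutive pairs (k, k+1) whose second-event times
    both fall in a period are checked.  Under the default ``printed``
    direction a pair violates iff the earlier arrival's second event came
    later AND its acuity number is greater (less urgent under KTAS); the
    ``urgency_first`` direction flips the acuity comparison to penalise a
    *more* urgent earlier arrival being served later.  The period rate is
    1 - violations / (cases in period - 1); periods with fewer than two
    evaluable cases map to None.
    """
    if direction not in ("printed", "urgency_first"):
        raise ValueError("direction must be 'printed' or 'urgency_first'")
    evaluable: list[tuple[int, int, int]] = []  # (t1, t2, emergency)
    for c in log.cases:
        eff = c.effective_events()
        if c.emergency is None or len(eff) < 2:
            continue
        evaluable.append((eff[0].timestamp, eff[1].timestamp, c.emergency))
    evaluable.sort(key=lambda t: t[0])
    if grid is None:
        if not evaluable:
            return {}
        t2s = [t2 for _, t2, _ in evaluable]
        grid = TimeGrid(origin=min(t2s), width=max(max(t2s) - min(t2s), 1) + 1,
                        n_bins=1)
    in_period: dict[int, int] = {j: 0 for j in range(grid.n_bins)}
    violations: dict[int, int] = {j: 0 for j in range(grid.n_bins)}
    for idx, (_, t2, emer) in enumerate(evaluable):
        j = grid.bin_of(t2)
        if j is None:
            continue
        in_period[j] += 1
        if idx + 1 < len(evaluable):
            _, t2_next, emer_next = evaluable[idx + 1]
            if grid.bin_of(t2_next) != j:
                continue
            later = t2 > t2_next
            worse = emer > emer_next if direction == "printed" else emer < emer_next
            if later and worse:
                violations[j] += 1
    return {
        j: (1.0 - violations[j] / (in_period[j] - 1)) if in_period[j] >= 2 else None
        for j in range(grid.n_bins)
    }


# ---------------------------------------------------------------------------
# Revisit rate
# ---------------------------------------------------------------------------


def revisit_rate(
    log: EventLog,
    window: int = 24 * 3600,
    *,
    mode: str = "end_to_start",
) -> float:
    """Fraction of revisit pairs per patient.

    Numerator: ordered same-patient case pairs (k earlier than l) whose
    separation is at most ``window`` seconds (inclusive); the separation is
    start-of-later minus end-of-earlier under the default ``end_to_start``
    mode (a revisit means coming back after leaving), or start-to-start
    under ``start_to_start``.  Denominator: distinct patients with an id.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if mode not in ("end_to_start", "start_to_start"):
        raise ValueError("mode must be 'end_to_start' or 'start_to_start'")
    by_patient: dict[str, list[Case]] = {}
    for c in log.cases:
        if c.patient_id is not None:
            by_patient.setdefault(c.patient_id, []).append(c)
    if not by_patient:
        return 0.0
    pairs = 0
    for cases in by_patient.values():
        cases.sort(key=lambda c: c.start_time)
        for k in range(len(cases)):
            for l in range(k + 1, len(cases)):
                ref = cases[k].end_time if mode == "end_to_start" \
                    else cases[k].start_time
                if cases[l].start_time - ref <= window:
                    pairs += 1
    return pairs / len(by_patient)
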