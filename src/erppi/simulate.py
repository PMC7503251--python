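"""Discrete-event simulator for ER event logs with exact ground truth.

The generator emulates the structure of a tertiary-hospital emergency
department extract: ~15 clinical activities, KTAS acuity levels 1-5,
day-peaked arrivals, hospitalization-vs-discharge pathway variants,
resources on day/night shifts, occasional same-patient revisits, and an
optional per-event cost.  Every case is driven by its own splittable
random stream, so a given patient's draws are identical regardless of the
total patient count and a fixed seed yields a byte-identical log.

Alongside the log the simulator returns a :class:`GroundTruth` object with
the *exact* (closed-form) expectations implied by the configuration --
mean length of stay overall / per acuity group / per terminal activity,
per-activity cycle-time means, variant probabilities, staffing per hour --
against which the indicator estimators can be checked.

:func:`inject_imperfections` plants the four classic data-imperfection
patterns (collateral duplicates, inadvertent time travel, form-based event
capture, same-day multi-visits under one case id) and returns a manifest,
so preprocessing can be verified to remove exactly what was planted.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .log import Case, Event, EventLog, EMERGENCY_GROUPS, norm_label
from .quality_indicators import TriageRuleTable, VitalFeatures, default_rule_table

logger = logging.getLogger("erppi")

MIN = 60  # seconds per minute


def group_of(level: int) -> str:
    """KTAS level -> named acuity group (severe/moderate/mild)."""
    for name, levels in EMERGENCY_GROUPS.items():
        if level in levels:
            return name
    raise ValueError(f"KTAS level {level} outside 1..5")


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ServiceTime:
    """Time-to-next-event distribution after an activity.

    ``family`` is ``exponential`` or ``fixed``; ``mean`` is in seconds.
    """

    family: str
    mean: float

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "fixed"):
            raise ValueError(f"unknown service-time family {self.family!r}")
        if self.mean <= 0:
            raise ValueError("service-time mean must be > 0")

    def sample(self, rng: np.random.Generator, scale: float) -> int:
        mean = self.mean * scale
        x = mean if self.family == "fixed" else rng.exponential(mean)
        return max(1, int(round(x)))

    def moments(self, scale: float) -> tuple[float, float]:
        """(mean, variance) in seconds under a group multiplier."""
        mean = self.mean * scale
        var = mean * mean if self.family == "exponential" else 0.0
        return mean, var


@dataclass(frozen=True)
class Pathway:
    """One clinical route: an activity sequence and its probability per
    acuity group (severe / moderate / mild)."""

    activities: tuple[str, ...]
    prob_by_group: Mapping[str, float]


@dataclass(frozen=True)
class Shift:
    """A staffing shift: resources named ``<name>_<i>`` working daily from
    ``start_hour`` (inclusive) to ``end_hour`` (exclusive), wrapping
    midnight when end < start."""

    name: str
    start_hour: int
    end_hour: int
    n_resources: int

    def covers(self, hour: int) -> bool:
        if self.start_hour < self.end_hour:
            return self.start_hour <= hour < self.end_hour
        return hour >= self.start_hour or hour < self.end_hour

    @property
    def resources(self) -> list[str]:
        return [f"{self.name}_{i + 1}" for i in range(self.n_resources)]


#: the 15 clinical activities of a typical ER extract
ACTIVITIES = (
    "Entry", "Basic Treatment", "First Aid Treatment", "Other Treatment",
    "Diagnostic Test", "Visual Test", "Consultation", "Cooperation Request",
    "Cooperation Arrival", "Decision on Hospitalization or Discharge",
    "Prescription Request", "Prescription Receiving", "Certificate Issuing",
    "Discharge", "Hospitalization",
)

_E, _BT, _FAT, _OT, _DT, _VT, _CO, _CRQ, _CAR, _DEC, _PRQ, _PRC, _CI, _DIS, _HOS = \
    ACTIVITIES

# admission probability per acuity group: severe patients are mostly admitted
_P_HOSP = {"severe": 0.9, "moderate": 0.6, "mild": 0.3}
# route mix within each terminal outcome (shared across groups)
_DISCHARGE_MIX = (0.35, 0.30, 0.20, 0.15)
_HOSP_MIX = (0.40, 0.30, 0.30)

_DISCHARGE_ROUTES = (
    (_E, _BT, _CO, _DT, _VT, _CO, _OT, _DT, _DEC, _PRQ, _PRC, _CI, _DIS),
    (_E, _FAT, _CO, _DT, _BT, _CO, _DEC, _PRQ, _PRC, _DIS),
    (_E, _BT, _CO, _DT, _OT, _VT, _CO, _DT, _CO, _DEC, _PRQ, _PRC, _CI, _DIS),
    (_E, _CO, _BT, _DT, _CO, _DEC, _PRC, _DIS),
)
_HOSP_ROUTES = (
    (_E, _BT, _CO, _DT, _VT, _OT, _CO, _CRQ, _CAR, _CO, _DT, _VT, _OT, _CO,
     _DEC, _PRQ, _PRC, _CI, _HOS),
    (_E, _FAT, _CO, _DT, _VT, _CO, _CRQ, _CAR, _DT, _CO, _DEC, _PRQ, _PRC,
     _CI, _HOS),
    (_E, _BT, _CO, _DT, _OT, _VT, _CO, _DT, _CO, _CRQ, _CAR, _CO, _DT, _OT,
     _CO, _DEC, _PRQ, _PRC, _CI, _HOS),
)


def _default_pathways() -> tuple[Pathway, ...]:
    paths = []
    for seq, w in zip(_DISCHARGE_ROUTES, _DISCHARGE_MIX):
        paths.append(Pathway(seq, {
            g: (1 - _P_HOSP[g]) * w for g in _P_HOSP
        }))
    for seq, w in zip(_HOSP_ROUTES, _HOSP_MIX):
        paths.append(Pathway(seq, {g: _P_HOSP[g] * w for g in _P_HOSP}))
    return tuple(paths)


#: time-to-next-event means, minutes (terminal activities need none)
_SERVICE_MINUTES = {
    _E: 20, _BT: 27, _FAT: 9, _OT: 20, _DT: 50, _VT: 15, _CO: 17,
    _CRQ: 30, _CAR: 60, _DEC: 100, _PRQ: 10, _PRC: 12, _CI: 8,
}

#: mean cost per activity (arbitrary currency units)
_COST_MEANS = {
    _E: 12.0, _BT: 45.0, _FAT: 30.0, _OT: 38.0, _DT: 120.0, _VT: 180.0,
    _CO: 60.0, _CRQ: 15.0, _CAR: 15.0, _DEC: 20.0, _PRQ: 8.0, _PRC: 25.0,
    _CI: 10.0, _DIS: 5.0, _HOS: 90.0,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground-truth scenario for the synthetic ER log.

    Defaults mirror a full-year tertiary-hospital extract: 30,000 patients
    over 365 days (~460k events), 15 activities, day-peaked arrivals,
    acuity mix whose severe/moderate/mild stay lengths average 11.8/8.9/6.0
    hours (~8.4 h overall; admitted ~10.5 h, discharged ~5.8 h), two daily
    shifts of 4 day and 2 night physicians, and a 0.38% same-day revisit
    probability.
    """

    n_patients: int = 30_000
    start: str = "2018-01-01"
    horizon_days: int = 365
    arrival_weights: tuple[float, ...] = (
        2.0, 1.5, 1.2, 1.0, 1.0, 1.2, 1.5, 2.0, 3.0, 4.0, 4.5, 5.0,
        5.0, 4.5, 4.5, 4.0, 4.0, 4.0, 4.5, 5.0, 4.5, 4.0, 3.0, 2.5,
    )
    ktas_mix: tuple[float, ...] = (0.03, 0.15, 0.45, 0.30, 0.07)
    pathways: tuple[Pathway, ...] = field(default_factory=_default_pathways)
    service_times: Mapping[str, ServiceTime] = field(
        default_factory=lambda: {
            a: ServiceTime("exponential", m * MIN)
            for a, m in _SERVICE_MINUTES.items()
        })
    group_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"severe": 1.490, "moderate": 1.272,
                                 "mild": 0.988})
    staffing: tuple[Shift, ...] = (
        Shift("doc_day", 8, 20, 4), Shift("doc_night", 20, 8, 2),
    )
    revisit_prob: float = 0.0038
    revisit_gap_hours: tuple[float, float] = (2.0, 20.0)
    cost_means: Mapping[str, float] | None = field(
        default_factory=lambda: dict(_COST_MEANS))
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be > 0")
        if self.horizon_days <= 0:
            raise ValueError("horizon_days must be > 0")
        if len(self.arrival_weights) != 24 or min(self.arrival_weights) <= 0:
            raise ValueError("arrival_weights must be 24 positive rates")
        if len(self.ktas_mix) != 5 or abs(sum(self.ktas_mix) - 1) > 1e-9:
            raise ValueError("ktas_mix must be 5 probabilities summing to 1")
        for g in ("severe", "moderate", "mild"):
            total = sum(p.prob_by_group.get(g, 0.0) for p in self.pathways)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"pathway probabilities for group {g!r} sum to {total}, not 1")
            if self.group_multipliers.get(g, 0) <= 0:
                raise ValueError(f"group_multipliers[{g!r}] must be > 0")
        for p in self.pathways:
            for a in p.activities[:-1]:
                if a not in self.service_times:
                    raise ValueError(f"no service time for activity {a!r}")
        if not 0 <= self.revisit_prob <= 1:
            raise ValueError("revisit_prob must be in [0, 1]")
        if not self.staffing:
            raise ValueError("staffing must name at least one shift")

    @property
    def start_epoch(self) -> int:
        return int(pd.Timestamp(self.start).value // 10**9)


# ---------------------------------------------------------------------------
# Exact expectations
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Closed-form expectations implied by a :class:`ScenarioConfig`."""

    mean_los_s: float
    std_los_s: float
    mean_los_by_group: dict[str, float]
    mean_los_by_terminal: dict[str, float]
    mean_cycle_time_s: dict[str, float]
    mean_initial_response_s: float
    variant_probs: dict[tuple[str, ...], float]
    staffing_per_hour: list[int]
    expected_revisit_rate: float
    mean_events_per_case: float


def ground_truth(config: ScenarioConfig) -> GroundTruth:
    """Exact indicator expectations for a scenario.

    LOS of a case on pathway *w* in group *g* is the sum of independent
    service times of all non-terminal activities, each with mean
    ``service_mean * multiplier[g]``; all quantities below are mixtures
    over (group, pathway) weights.
    """
    config.validate()
    p_group = {
        g: sum(config.ktas_mix[lvl - 1] for lvl in levels)
        for g, levels in EMERGENCY_GROUPS.items()
    }
    weights: list[tuple[str, Pathway, float]] = [
        (g, path, p_group[g] * path.prob_by_group.get(g, 0.0))
        for g in p_group for path in config.pathways
    ]

    def path_moments(path: Pathway, g: str) -> tuple[float, float]:
        mult = config.group_multipliers[g]
        mean = var = 0.0
        for a in path.activities[:-1]:
            m, v = config.service_times[a].moments(mult)
            mean += m
            var += v
        return mean, var

    mean_los = m2 = 0.0
    by_group: dict[str, float] = {g: 0.0 for g in p_group}
    by_terminal_num: dict[str, float] = {}
    by_terminal_den: dict[str, float] = {}
    ct_num: dict[str, float] = {}
    ct_den: dict[str, float] = {}
    variant_probs: dict[tuple[str, ...], float] = {}
    mean_len = 0.0
    for g, path, w in weights:
        mean, var = path_moments(path, g)
        mean_los += w * mean
        m2 += w * (var + mean * mean)
        by_group[g] += w * mean
        term = norm_label(path.activities[-1])
        by_terminal_num[term] = by_terminal_num.get(term, 0.0) + w * mean
        by_terminal_den[term] = by_terminal_den.get(term, 0.0) + w
        mult = config.group_multipliers[g]
        for a in path.activities[:-1]:
            ct_num[a] = ct_num.get(a, 0.0) + w * config.service_times[a].mean * mult
            ct_den[a] = ct_den.get(a, 0.0) + w
        variant_probs[path.activities] = variant_probs.get(path.activities, 0.0) + w
        mean_len += w * len(path.activities)
    for g in by_group:
        by_group[g] /= p_group[g]
    entry_key = next(a for a in ct_num if norm_label(a) == "entry")
    return GroundTruth(
        mean_los_s=mean_los,
        std_los_s=math.sqrt(m2 - mean_los * mean_los),
        mean_los_by_group=by_group,
        mean_los_by_terminal={
            t: by_terminal_num[t] / by_terminal_den[t] for t in by_terminal_num
        },
        mean_cycle_time_s={a: ct_num[a] / ct_den[a] for a in ct_num},
        mean_initial_response_s=ct_num[entry_key] / ct_den[entry_key],
        variant_probs=variant_probs,
        staffing_per_hour=[
            sum(s.n_resources for s in config.staffing if s.covers(h))
            for h in range(24)
        ],
        expected_revisit_rate=config.revisit_prob,
        mean_events_per_case=mean_len,
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_log(config: ScenarioConfig | None = None
                 ) -> tuple[EventLog, GroundTruth]:
    """Generate a synthetic ER event log plus its exact ground truth.

    Each patient arrives on a uniformly drawn day at an hour drawn from the
    day-peaked arrival profile, receives an acuity level, follows a drawn
    pathway with accumulated service times (whole seconds, minimum 1 s
    apart, so timestamps within a case are strictly increasing and a clean
    log never triggers any imperfection remedy), and is served by
    uniformly chosen on-shift resources.  With probability ``revisit_prob``
    the patient returns 2-20 h after leaving for a second, independently
    drawn episode.
    """
    config = config or ScenarioConfig()
    config.validate()
    gt = ground_truth(config)
    groups = ("severe", "moderate", "mild")
    paths_by_group = {
        g: ([p.activities for p in config.pathways],
            np.array([p.prob_by_group.get(g, 0.0) for p in config.pathways]))
        for g in groups
    }
    shift_resources = {s.name: s.resources for s in config.staffing}
    hour_shifts = [
        [s for s in config.staffing if s.covers(h)] for h in range(24)
    ]
    arrival_p = np.asarray(config.arrival_weights, dtype=float)
    arrival_p = arrival_p / arrival_p.sum()
    ktas_p = np.asarray(config.ktas_mix, dtype=float)
    start_epoch = config.start_epoch

    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    cases: list[Case] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{i + 1:06d}"
        day = int(rng.integers(config.horizon_days))
        hour = int(rng.choice(24, p=arrival_p))
        arrival = start_epoch + day * 86400 + hour * 3600 + int(rng.integers(3600))
        n_visits = 2 if rng.random() < config.revisit_prob else 1
        for visit in range(n_visits):
            ktas = int(rng.choice(5, p=ktas_p)) + 1
            g = group_of(ktas)
            mult = config.group_multipliers[g]
            seqs, probs = paths_by_group[g]
            seq = seqs[int(rng.choice(len(seqs), p=probs))]
            ts = arrival
            events: list[Event] = []
            for j, act in enumerate(seq):
                h = (ts // 3600) % 24
                on_shift = hour_shifts[h]
                shift = on_shift[int(rng.integers(len(on_shift)))] if on_shift \
                    else config.staffing[0]
                res = shift_resources[shift.name][
                    int(rng.integers(shift.n_resources))]
                cost = None
                if config.cost_means is not None and act in config.cost_means:
                    cost = round(float(
                        rng.gamma(4.0, config.cost_means[act] / 4.0)), 2)
                events.append(Event(activity=act, timestamp=int(ts),
                                    originator=res, cost=cost))
                if j < len(seq) - 1:
                    ts += config.service_times[act].sample(rng, mult)
            cases.append(Case(
                case_id=f"{pid}-V{visit + 1}", events=events,
                patient_id=pid, emergency=ktas,
            ))
            if visit + 1 < n_visits:
                lo, hi = config.revisit_gap_hours
                arrival = ts + int(rng.uniform(lo * 3600, hi * 3600))
    log = EventLog(cases=cases)
    logger.info("simulate_log patients=%d cases=%d events=%d",
                config.n_patients, len(log),
                sum(len(c.events) for c in log.cases))
    return log, gt


# ---------------------------------------------------------------------------
# Vitals consistent with a triage rule table
# ---------------------------------------------------------------------------

# "safe" bands that trigger no rule of the default table
_SAFE_BANDS = {
    "gcs": (15.0, 15.0), "spo2": (96.0, 100.0), "sbp": (100.0, 140.0),
    "pulse": (60.0, 95.0), "resp": (12.0, 20.0), "temp": (36.0, 37.2),
    "pain": (0.0, 0.0),
}
# per level, the candidate single-trigger bands (feature -> sampling band)
# that classify as exactly that level under the default table
_TRIGGER_BANDS: dict[int, dict[str, tuple[float, float]]] = {
    1: {"gcs": (3.0, 8.0), "spo2": (70.0, 84.5), "sbp": (50.0, 69.5)},
    2: {"gcs": (9.0, 12.0), "spo2": (85.5, 89.5), "pain": (8.0, 10.0),
        "pulse": (131.0, 160.0), "resp": (31.0, 40.0), "temp": (40.0, 41.5)},
    3: {"gcs": (13.0, 14.0), "spo2": (90.5, 93.5), "pain": (4.0, 7.0),
        "pulse": (111.0, 129.0), "resp": (25.0, 30.0), "temp": (38.5, 39.9),
        "sbp": (181.0, 220.0)},
    4: {"pain": (1.0, 3.5), "pulse": (101.0, 109.5), "temp": (37.5, 38.4)},
    5: {},
}


@dataclass
class VitalsGroundTruth:
    expected_accuracy: float
    n_noised: int


def _sample_vitals_for_level(rng: np.random.Generator, level: int,
                             table: TriageRuleTable) -> VitalFeatures:
    values = {f: float(rng.uniform(lo, hi)) for f, (lo, hi) in _SAFE_BANDS.items()}
    triggers = _TRIGGER_BANDS[level]
    if triggers:
        feat = sorted(triggers)[int(rng.integers(len(triggers)))]
        lo, hi = triggers[feat]
        values[feat] = float(rng.uniform(lo, hi))
    vitals = VitalFeatures(**values)
    got = table.classify(vitals)
    if got != level:
        raise ValueError(
            f"vitals sampler is tuned to the default rule table; the supplied "
            f"table classified a level-{level} template as {got}"
        )
    return vitals


def simulate_vitals(
    log: EventLog,
    rule_table: TriageRuleTable | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[EventLog, VitalsGroundTruth]:
    """Attach triage vitals consistent with each case's recorded acuity.

    Vitals are sampled so the rule table maps them to the recorded KTAS
    level.  With probability ``noise`` a case's *recorded* level is
    re-drawn uniformly from the other four levels (the vitals keep pointing
    at the original level), so the expected rule-table triage accuracy is
    exactly ``1 - noise``.
    """
    if not 0 <= noise <= 1:
        raise ValueError("noise must be in [0, 1]")
    table = rule_table or default_rule_table()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x517A)))
    cases: list[Case] = []
    n_noised = 0
    for c in log.cases:
        if c.emergency is None:
            cases.append(c)
            continue
        vitals = _sample_vitals_for_level(rng, c.emergency, table)
        emergency = c.emergency
        if noise > 0 and rng.random() < noise:
            others = [lv for lv in (1, 2, 3, 4, 5) if lv != emergency]
            emergency = others[int(rng.integers(4))]
            n_noised += 1
        attrs = dict(c.attrs)
        attrs["vitals"] = vitals
        cases.append(Case(c.case_id, c.events, c.patient_id, emergency, attrs))
    return EventLog(cases=cases), VitalsGroundTruth(
        expected_accuracy=1.0 - noise, n_noised=n_noised)


# ---------------------------------------------------------------------------
# Imperfection injection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImperfectionConfig:
    """How many of each data-imperfection pattern to plant."""

    collateral_dup_rate: float = 0.0
    time_travel_case_count: int = 0
    form_based_case_count: int = 0
    multi_visit_same_day_count: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.collateral_dup_rate <= 1:
            raise ValueError("collateral_dup_rate must be in [0, 1]")
        for f in ("time_travel_case_count", "form_based_case_count",
                  "multi_visit_same_day_count"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


def inject_imperfections(
    log: EventLog,
    config: ImperfectionConfig,
    seed: int = 0,
) -> tuple[EventLog, dict]:
    """Plant imperfection patterns into a (clean) log.

    Returns the dirtied log and a manifest naming every artifact:
    ``time_travel`` / ``form_based`` case ids (targets of whole-case
    deletion), ``collateral`` duplicated events (case_id, activity,
    timestamp), and ``multi_visit`` patient ids whose two same-day visits
    were merged under one case id (target of visit-based re-casing).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x1117)))
    cases = [Case(c.case_id, list(c.events), c.patient_id, c.emergency,
                  dict(c.attrs)) for c in log.cases]
    manifest: dict = {"time_travel": [], "form_based": [], "collateral": [],
                      "multi_visit": []}

    eligible = [i for i, c in enumerate(cases) if len(c.events) >= 4]
    need = config.time_travel_case_count + config.form_based_case_count
    if need > len(eligible):
        raise ValueError(
            f"cannot plant {need} deletion patterns in {len(eligible)} "
            "eligible cases")
    picked = rng.choice(len(eligible), size=need, replace=False) if need else []
    picked_ids = [eligible[int(k)] for k in picked]
    tt_ids = picked_ids[:config.time_travel_case_count]
    fb_ids = picked_ids[config.time_travel_case_count:]

    for idx in tt_ids:
        c = cases[idx]
        j = 1 + int(rng.integers(len(c.events) - 1))
        e = c.events[j]
        early = c.events[0].timestamp - int(rng.integers(60, 3600))
        c.events[j] = replace(e, timestamp=early)
        cases[idx] = Case(c.case_id, c.events, c.patient_id, c.emergency, c.attrs)
        manifest["time_travel"].append(c.case_id)

    for idx in fb_ids:
        c = cases[idx]
        # three distinct non-entry activities collapsed onto one instant
        seen: dict[str, int] = {}
        for j in range(1, len(c.events)):
            seen.setdefault(norm_label(c.events[j].activity), j)
            if len(seen) == 3:
                break
        if len(seen) < 3:
            raise ValueError(
                f"case {c.case_id!r} lacks 3 distinct non-entry activities")
        anchor = min(c.events[j].timestamp for j in seen.values())
        for j in seen.values():
            c.events[j] = replace(c.events[j], timestamp=anchor)
        cases[idx] = Case(c.case_id, c.events, c.patient_id, c.emergency, c.attrs)
        manifest["form_based"].append(c.case_id)

    if config.collateral_dup_rate > 0:
        for c in cases:
            out: list[Event] = []
            for e in c.events:
                out.append(e)
                if rng.random() < config.collateral_dup_rate:
                    out.append(replace(e))
                    manifest["collateral"].append(
                        {"case_id": c.case_id, "activity": e.activity,
                         "timestamp": e.timestamp})
            c.events[:] = out

    if config.multi_visit_same_day_count:
        singles = [i for i, c in enumerate(cases)
                   if c.patient_id is not None and i not in set(picked_ids)]
        by_pid: dict[str, list[int]] = {}
        for i in singles:
            by_pid.setdefault(cases[i].patient_id, []).append(i)
        candidates = sorted(pid for pid, idxs in by_pid.items()
                            if len(idxs) == 1)
        if config.multi_visit_same_day_count > len(candidates):
            raise ValueError("not enough single-visit patients for "
                             "multi_visit_same_day_count")
        chosen = rng.choice(len(candidates),
                            size=config.multi_visit_same_day_count,
                            replace=False)
        for k in chosen:
            pid = candidates[int(k)]
            i = by_pid[pid][0]
            c = cases[i]
            sep = int(rng.uniform(6 * 3600, 10 * 3600))
            base = c.events[-1].timestamp + sep
            extra = [replace(e, timestamp=base + j * 60)
                     for j, e in enumerate(c.events)]
            cases[i] = Case(c.case_id, c.events + extra, c.patient_id,
                            c.emergency, c.attrs)
            manifest["multi_visit"].append(pid)

    dirty = EventLog(cases=[Case(c.case_id, c.events, c.patient_id,
                                 c.emergency, c.attrs) for c in cases])
    return dirty, manifest
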