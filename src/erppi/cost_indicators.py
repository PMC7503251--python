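"""Cost-perspective indicators.

Clinical extracts come in two kinds: cost-attached (each event may carry a
cost) and cost-detached.  For the former, :func:`total_cost` sums event
costs per case; for the latter the indirect indicator
:func:`originator_count` (distinct clinicians, under the assumption that
all resources are full-time workers) applies.  :func:`resources_per_period`
profiles staffing and patient census over an hourly (or any) time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .log import EventLog, log_intervals


class CostDetachedError(ValueError):
    """Raised when a cost indicator is requested on a log without costs."""


@dataclass(frozen=True)
class TimeGrid:
    """Half-open time bins [origin + j*width, origin + (j+1)*width).

    Left-closed: an instant exactly on a boundary belongs to the later bin.
    """

    origin: int
    width: int
    n_bins: int

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("grid width must be > 0")
        if self.n_bins <= 0:
            raise ValueError("grid must have at least one bin")

    @classmethod
    def covering(cls, log: EventLog, width: int = 3600) -> "TimeGrid":
        """Smallest grid of the given width covering the log span, aligned
        to a multiple of the width."""
        lo, hi = log.span
        origin = (lo // width) * width
        n_bins = (hi - origin) // width + 1
        return cls(origin=origin, width=width, n_bins=int(n_bins))

    @property
    def end(self) -> int:
        return self.origin + self.n_bins * self.width

    def bin_of(self, ts: int) -> int | None:
        """Bin index containing *ts*, or None if outside the grid."""
        if ts < self.origin or ts >= self.end:
            return None
        return int((ts - self.origin) // self.width)

    def bin_starts(self) -> np.ndarray:
        return self.origin + self.width * np.arange(self.n_bins)

    def overlapping_bins(self, start: int, end: int) -> range:
        """Bin indices whose half-open interval intersects [start, end].

        A zero-length interval [t, t] overlaps exactly the bin containing t.
        """
        if end < start:
            raise ValueError("interval end before start")
        lo = max(0, (start - self.origin) // self.width)
        hi = min(self.n_bins - 1, (end - self.origin) // self.width)
        if hi < lo:
            return range(0)
        return range(int(lo), int(hi) + 1)


@dataclass(frozen=True, slots=True)
class CostSample:
    """Total cost of one case plus the count of cost-less events."""

    case_id: str
    value: float
    n_missing_cost: int


def total_cost(log: EventLog) -> list[CostSample]:
    """Per-case sum of event costs; events without a cost contribute 0 and
    are counted.  Raises on a cost-detached log (no event carries a cost)."""
    if not any(e.cost is not None for e in log.iter_events()):
        raise CostDetachedError("cost-detached log; use originator_count")
    out = []
    for c in log.cases:
        costs = [e.cost for e in c.events if e.cost is not None]
        out.append(CostSample(c.case_id, float(sum(costs)),
                              len(c.events) - len(costs)))
    return out


def originator_count(log: EventLog) -> int:
    """Number of distinct originator labels over all events."""
    return len({e.originator for e in log.iter_events() if e.originator is not None})


@dataclass
class PresenceProfile:
    """Per-bin staffing and patient census series."""

    grid: TimeGrid
    resource_count: np.ndarray  # distinct originators active in each bin
    patient_count: np.ndarray   # cases whose [first, last] interval overlaps


def resources_per_period(
    log: EventLog,
    grid: TimeGrid | None = None,
    resource_filter: set[str] | None = None,
) -> PresenceProfile:
    """Count distinct working resources and present patients per time bin.

    A resource is active in a bin if at least one of its event intervals
    (inferred start to complete) overlaps the bin; a patient is present if
    the case's [first event, last event] interval overlaps the bin.
    """
    grid = grid or TimeGrid.covering(log)
    active: list[set[str]] = [set() for _ in range(grid.n_bins)]
    patients = np.zeros(grid.n_bins, dtype=int)
    intervals = log_intervals(log)
    for case in log.cases:
        for j in grid.overlapping_bins(case.start_time, case.end_time):
            patients[j] += 1
        for iv in intervals[case.case_id]:
            res = iv.event.originator
            if res is None:
                continue
            if resource_filter is not None and res not in resource_filter:
                continue
            for j in grid.overlapping_bins(iv.start, iv.complete):
                active[j].add(res)
    return PresenceProfile(
        grid=grid,
        resource_count=np.array([len(s) for s in active], dtype=int),
        patient_count=patients,
    )


def presence_to_rows(profile: PresenceProfile) -> list[dict]:
    """Tidy rows (period_start ISO seconds, resource_count, patient_count)."""
    import pandas as pd

    rows = []
    for start, rc, pc in zip(profile.grid.bin_starts(),
                             profile.resource_count, profile.patient_count):
        rows.append({
            "period_start": pd.Timestamp(int(start), unit="s").isoformat(),
            "resource_count": int(rc),
            "patient_count": int(pc),
        })
    return rows
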