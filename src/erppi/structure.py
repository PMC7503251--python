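"""Process-structure analysis: direct-follows graphs, flexibility
indicators, and dotted-chart export.

The direct-follows graph (DFG) records, for every consecutive event pair
within a case, the ordered activity pair with its frequency and the time
gaps observed -- the standard performance-annotated process map.  The two
flexibility indicators are the number of distinct trace variants and the
number of distinct direct-follows relations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .log import EventLog, aggregate, norm_label


@dataclass
class EdgeStats:
    frequency: int = 0
    durations: list[float] = field(default_factory=list)

    @property
    def avg_duration(self) -> float:
        return aggregate(self.durations, "avg")

    @property
    def med_duration(self) -> float:
        return aggregate(self.durations, "med")


@dataclass
class DFG:
    """Direct-follows graph with per-edge frequency and duration samples."""

    nodes: set[str]
    edges: dict[tuple[str, str], EdgeStats]


def build_dfg(log: EventLog) -> DFG:
    """Build the DFG over the effective events of every case: each
    consecutive pair (a_i, a_{i+1}) increments the edge and records the
    gap t_{i+1} - t_i in seconds."""
    if len(log) == 0:
        raise ValueError("cannot build a DFG from an empty log")
    nodes: set[str] = set()
    edges: dict[tuple[str, str], EdgeStats] = {}
    for case in log.cases:
        eff = case.effective_events()
        prev = None
        for e in eff:
            label = log.canonical_label(e.activity) or e.activity
            nodes.add(label)
            if prev is not None:
                key = (prev[0], label)
                stats = edges.setdefault(key, EdgeStats())
                stats.frequency += 1
                stats.durations.append(float(e.timestamp - prev[1]))
            prev = (label, e.timestamp)
    return DFG(nodes=nodes, edges=edges)


def relation_count(dfg: DFG) -> int:
    """Number of distinct direct-follows relations (edges with freq >= 1)."""
    return sum(1 for s in dfg.edges.values() if s.frequency >= 1)


def variant_count(log: EventLog) -> int:
    """Number of distinct trace variants over the log's cases."""
    return len({tuple(norm_label(a) for a in c.variant()) for c in log.cases})


def filter_edges(dfg: DFG, top_fraction: float) -> DFG:
    """Keep the most frequent fraction of edges (display filtering only;
    the flexibility indicator uses the unfiltered graph)."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    ranked = sorted(dfg.edges.items(), key=lambda kv: -kv[1].frequency)
    keep = max(1, int(round(top_fraction * len(ranked))))
    edges = dict(ranked[:keep])
    nodes = {a for a, _ in edges} | {b for _, b in edges}
    return DFG(nodes=nodes, edges=edges)


def dfg_to_dot(dfg: DFG) -> str:
    """Serialize as a DOT digraph with frequency/avg-duration edge labels."""
    lines = ["digraph dfg {"]
    for node in sorted(dfg.nodes):
        lines.append(f'  "{node}";')
    for (a, b), s in sorted(dfg.edges.items()):
        label = f"{s.frequency} ({s.avg_duration / 60:.1f} m)"
        lines.append(f'  "{a}" -> "{b}" [label="{label}"];')
    lines.append("}")
    return "\n".join(lines)


def dfg_to_rows(dfg: DFG) -> list[dict]:
    """Tidy rows: source, target, frequency, avg_duration, med_duration
    (durations in seconds)."""
    return [
        {
            "source": a,
            "target": b,
            "frequency": s.frequency,
            "avg_duration": s.avg_duration,
            "med_duration": s.med_duration,
        }
        for (a, b), s in sorted(dfg.edges.items())
    ]


@dataclass(frozen=True, slots=True)
class DotPoint:
    """One dotted-chart point: case rank (by first event time), event
    timestamp, and the colour key."""

    case_rank: int
    case_id: str
    timestamp: int
    color: str


#: KTAS level -> conventional dotted-chart colour (urgent = red)
KTAS_COLORS = {1: "red", 2: "red", 3: "yellow", 4: "green", 5: "purple"}


def dotted_chart_data(log: EventLog, color_by: str = "emergency"
                      ) -> list[DotPoint]:
    """One point per effective event, cases ranked by first-event time.

    ``color_by`` is one of ``emergency`` (KTAS urgency-group colours),
    ``variant`` or ``activity``.
    """
    if color_by not in ("emergency", "variant", "activity"):
        raise ValueError(
            f"unknown colour attribute {color_by!r}; "
            "choose emergency, variant or activity"
        )
    ranked = sorted(log.cases, key=lambda c: c.start_time)
    points: list[DotPoint] = []
    for rank, case in enumerate(ranked):
        if color_by == "emergency":
            color = KTAS_COLORS.get(case.emergency, "grey")  # type: ignore[arg-type]
        elif color_by == "variant":
            color = ">".join(case.variant())
        for e in case.effective_events():
            if color_by == "activity":
                color = e.activity
            points.append(DotPoint(rank, case.case_id, e.timestamp, color))
    return points
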