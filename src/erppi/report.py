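"""Consolidated 16-indicator report.

:func:`run_all` executes preprocessing and every indicator the input log
supports; indicators whose required data is absent (event costs, triage
vitals, a reference stochastic language) are reported as
``not computable: <reason>`` rather than failing the run, mirroring how a
real extract often supports only a subset.  Report units follow clinical
convention: hours for the stay-length family, minutes for cycle/response
times.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .cost_indicators import (
    CostDetachedError,
    TimeGrid,
    originator_count,
    resources_per_period,
    total_cost,
)
from .log import (
    DEFAULT_CONSULTATION_LABEL,
    DEFAULT_ENTRY_LABEL,
    DEFAULT_FORM_THRESHOLD,
    EventLog,
    aggregate,
    preprocess,
    read_csv_log,
)
from .quality_indicators import (
    StochasticLanguage,
    TriageRuleTable,
    log_language,
    los_std,
    matching_rate,
    triage_accuracy,
    triage_response_rate,
    revisit_rate,
    workload,
)
from .structure import build_dfg, relation_count, variant_count
from .time_indicators import (
    cycle_time,
    door_to_doctor_time,
    initial_response_time,
    los,
    los_by_emergency,
    los_by_variant,
    summarize,
    terminal_selector,
)

logger = logging.getLogger("erppi")

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class ReportConfig:
    """Knobs of the consolidated report."""

    entry_label: str = DEFAULT_ENTRY_LABEL
    consultation_label: str = DEFAULT_CONSULTATION_LABEL
    form_threshold: int = DEFAULT_FORM_THRESHOLD
    preprocess: bool = True
    grid_width_s: int = 3600          # workload / staffing bins
    response_period_s: int = 86400    # response-rate periods
    revisit_window_s: int = 86400
    terminal_labels: tuple[str, ...] = ("Hospitalization", "Discharge")
    reference_language: str | None = None   # path to a variant/probability CSV
    rule_table: str | None = None           # path to a triage rule JSON
    seed: int = 0

    def to_dict(self) -> dict:
        return {k: list(v) if isinstance(v, tuple) else v
                for k, v in self.__dict__.items()}

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _not_computable(reason: str) -> dict:
    return {"status": f"not computable: {reason}"}


def _ok(block: dict) -> dict:
    return {"status": "ok", **block}


def run_all(
    log: EventLog | str | Path,
    config: ReportConfig | None = None,
    *,
    classifier=None,
) -> dict:
    """Compute the full indicator report for a log (object or CSV path).

    Returns a JSON-serialisable dict with one block per indicator
    (ERPPIT1..ERPPIF2) plus provenance and a preprocessing summary.
    """
    config = config or ReportConfig()
    t0 = time.perf_counter()
    source = None
    if not isinstance(log, EventLog):
        source = str(log)
        log = read_csv_log(log)
    if len(log) == 0:
        raise ValueError("empty log: nothing to report")

    pre_summary: dict = {"enabled": config.preprocess}
    if config.preprocess:
        log, summary = preprocess(log, config.entry_label, config.form_threshold)
        pre_summary.update(summary)
        if len(log) == 0:
            raise ValueError("preprocessing removed every case")

    report: dict = {}

    # ---- time perspective ------------------------------------------------
    report["ERPPIT1"] = _ok({"name": "length_of_stay",
                             **summarize(los(log), "h")})

    t2: dict = {"name": "length_of_stay_by_variant"}
    for label in config.terminal_labels:
        samples = los_by_variant(log, terminal_selector(label))
        t2[label.lower().replace(" ", "_")] = summarize(samples, "h")
    report["ERPPIT2"] = _ok(t2)

    if any(c.emergency is not None for c in log.cases):
        t3: dict = {"name": "length_of_stay_by_acuity"}
        for preset in ("severe", "moderate", "mild"):
            samples, excluded = los_by_emergency(log, preset)
            t3[preset] = summarize(samples, "h")
        t3["unlabelled_cases"] = excluded
        report["ERPPIT3"] = _ok(t3)
    else:
        report["ERPPIT3"] = _not_computable("no triage acuity values in log")

    t4: dict = {"name": "activity_cycle_time"}
    for act in sorted(log.activity_alphabet):
        samples = cycle_time(log, act)
        if samples:
            t4[act] = summarize(samples, "m")
    report["ERPPIT4"] = _ok(t4)

    if log.canonical_label(config.entry_label) is not None:
        samples, skipped = initial_response_time(log, config.entry_label)
        report["ERPPIT5"] = _ok({"name": "initial_response_time",
                                 **summarize(samples, "m", skipped=skipped)})
    else:
        report["ERPPIT5"] = _not_computable(
            f"entry activity {config.entry_label!r} not in log")

    if (log.canonical_label(config.entry_label) is not None
            and log.canonical_label(config.consultation_label) is not None):
        samples, skipped = door_to_doctor_time(
            log, config.entry_label, config.consultation_label)
        report["ERPPIT6"] = _ok({"name": "door_to_doctor_time",
                                 **summarize(samples, "m", skipped=skipped)})
    else:
        report["ERPPIT6"] = _not_computable(
            "entry and/or consultation activity not in log")

    # ---- cost perspective ------------------------------------------------
    try:
        costs = total_cost(log)
        values = [c.value for c in costs]
        report["ERPPIC1"] = _ok({
            "name": "total_cost_per_case", "n": len(values), "unit": "currency",
            **{f: aggregate(values, f) for f in ("avg", "med", "min", "max")},
            "events_without_cost": sum(c.n_missing_cost for c in costs),
        })
    except CostDetachedError as exc:
        report["ERPPIC1"] = _not_computable(str(exc))

    report["ERPPIC2"] = _ok({"name": "originator_count",
                             "value": originator_count(log)})

    # ---- quality perspective ---------------------------------------------
    if len(log) >= 2:
        q1: dict = {"name": "los_std", "unit": "h",
                    "value": los_std(log) / SECONDS_PER_HOUR}
        for label in config.terminal_labels:
            try:
                q1[label.lower().replace(" ", "_")] = (
                    los_std(log, terminal_activity=label) / SECONDS_PER_HOUR)
            except ValueError:
                pass
        report["ERPPIQ1"] = _ok(q1)
    else:
        report["ERPPIQ1"] = _not_computable("fewer than 2 cases")

    resources = sorted({e.originator for e in log.iter_events()
                        if e.originator is not None})
    if resources:
        grid = TimeGrid.covering(log, config.grid_width_s)
        per_resource = {}
        for r in resources:
            series = workload(log, r, grid).values
            per_resource[r] = {"avg": float(series.mean()),
                               "max": int(series.max())}
        report["ERPPIQ2"] = _ok({
            "name": "resource_workload",
            "unit": f"open events per {config.grid_width_s}s bin",
            "n_resources": len(resources),
            "avg_over_resources": float(np.mean(
                [v["avg"] for v in per_resource.values()])),
            "per_resource": per_resource,
        })
    else:
        report["ERPPIQ2"] = _not_computable("no originators in log")

    if config.reference_language is not None:
        model = StochasticLanguage.from_csv(config.reference_language)
        report["ERPPIQ3"] = _ok({
            "name": "matching_rate",
            "value": matching_rate(log_language(log), model),
        })
    else:
        report["ERPPIQ3"] = _not_computable("no reference model language given")

    has_vitals = any(c.attrs.get("vitals") is not None for c in log.cases)
    rule_classifier = classifier
    if rule_classifier is None and config.rule_table is not None:
        rule_classifier = TriageRuleTable.from_json(config.rule_table).classify
    if has_vitals and rule_classifier is not None:
        result = triage_accuracy(log, rule_classifier)
        report["ERPPIQ4"] = _ok({
            "name": "triage_accuracy",
            "value": result.accuracy,
            "n": result.n_evaluated,
            "excluded": result.n_excluded,
            "confusion": result.confusion.tolist(),
        })
    else:
        report["ERPPIQ4"] = _not_computable(
            "triage vitals and/or rule table unavailable")

    if any(c.emergency is not None for c in log.cases):
        lo, hi = log.span
        grid = TimeGrid(origin=lo, width=config.response_period_s,
                        n_bins=(hi - lo) // config.response_period_s + 1)
        rates = triage_response_rate(log, grid)
        defined = [r for r in rates.values() if r is not None]
        if defined:
            report["ERPPIQ5"] = _ok({
                "name": "triage_response_rate",
                "avg": float(np.mean(defined)),
                "min": float(np.min(defined)),
                "n_periods": len(defined),
            })
        else:
            report["ERPPIQ5"] = _not_computable(
                "no period with 2+ evaluable cases")
    else:
        report["ERPPIQ5"] = _not_computable("no triage acuity values in log")

    if any(c.patient_id is not None for c in log.cases):
        report["ERPPIQ6"] = _ok({
            "name": "revisit_rate",
            "value": revisit_rate(log, config.revisit_window_s),
            "window_s": config.revisit_window_s,
        })
    else:
        report["ERPPIQ6"] = _not_computable("no patient identifiers in log")

    # ---- flexibility perspective -----------------------------------------
    report["ERPPIF1"] = _ok({"name": "variant_count",
                             "value": variant_count(log)})
    report["ERPPIF2"] = _ok({"name": "relation_count",
                             "value": relation_count(build_dfg(log))})

    report["provenance"] = {
        "tool": "erppi",
        "version": __version__,
        "input": source,
        "config_hash": config.config_hash,
        "preprocessing": pre_summary,
        "cases": len(log),
        "events": sum(len(c.events) for c in log.cases),
    }
    logger.info("run_all cases=%d elapsed=%.2fs", len(log),
                time.perf_counter() - t0)
    return report


def report_to_json(report: dict) -> str:
    """Canonical JSON serialisation (sorted keys) of a report."""
    return json.dumps(report, indent=2, sort_keys=True)
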