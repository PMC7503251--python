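# Methods

This note records the modelling assumptions, numerical choices and known
limitations behind `erppi`, in the spirit of a model-description appendix.

## Event-log model

A log is a multiset of traces; each case holds an ordered event sequence
with stable timestamp sorting (ties keep input order, since clinical
extracts define no secondary key).  Timestamps are timezone-naive seconds
since the epoch internally; reports convert to hours for the stay-length
family and minutes for cycle/response times, following clinical
convention.

**Lifecycle handling.**  ER extracts are usually complete-only, but rows
typed `start` do occur.  The package treats a start event that has a later
matching complete of the same activity in the same case as lifecycle
metadata: the pair forms one interval and the complete event stands for
it.  A start event with *no* matching complete is promoted to an
instantaneous event — the system recorded only the initiation, and
dropping it would silently delete performed work (e.g. a consultation
begun just before data extraction).  Variants, stay lengths, cycle times
and the direct-follows graph are all computed over this "effective event"
projection.

**Start-time inference.**  Where only complete events exist, the start of
event *i* (*i* > 1) is taken as the complete time of event *i−1*, and the
first event of a case has zero duration.  This is the standard inference
for complete-only logs and is what the workload and staffing-presence
computations consume.  Explicitly recorded start/complete pairs keep
their recorded interval.

**Label handling.**  Activity and configuration labels are compared
case-insensitively after trimming; the log's first-seen spelling is
canonical for output.  The entry and consultation activity names are
configuration (defaults `entry`, `consultation`), not constants.

## Preprocessing remedies

Four imperfection patterns are handled, all deletion- or
collapse-based (partial repair is deliberately not attempted, as the
correct repair is rarely inferable from the log alone):

* **Collateral events** — within a case, events identical on (activity,
  timestamp, type, originator) collapse to the first copy.
* **Inadvertent time travel** — a case is deleted when any event predates
  its first entry event.
* **Form-based event capture** — a case is deleted when at least
  *k* distinct activities share one identical timestamp; the default
  multiplicity k = 3 keeps legitimate same-minute pairs while catching
  form submissions, and is configurable.
* **Exclusive case** — when patient ids were reused as case ids,
  `rebuild_cases` re-partitions each patient's pooled events into visits
  wherever consecutive events are more than a gap apart (default 24 h;
  pass a smaller gap when same-day revisits are the concern).

Both deletion remedies are idempotent and conserve cases
(kept + removed = input).  The pipeline order is deduplicate first, then
delete, so duplicate counts are reported even for cases later removed.

## Indicator definitions and numerical choices

* **Aggregation** — every duration indicator reports AVG/MED/MIN/MAX plus
  n; the spread indicator uses the population standard deviation
  (ddof = 0, configurable), treating the log as the complete population of
  episodes rather than a sample.
* **Door-To-Doctor time** — first entry to *first* consultation at or
  after it (configurable to last), matching the clinical reading of the
  metric; consultations before the arrival timestamp are a time-travel
  artifact and are ignored.
* **Time grids** — half-open, left-closed bins; an instant exactly on a
  boundary belongs to the later bin.  A zero-length interval overlaps
  exactly the bin containing it.
* **Workload** — per bin, events started minus events completed by the
  resource, accumulated; satisfies the recursion
  `WL_j = WL_{j-1} + started_j − completed_j` and telescopes to
  total started − total completed at the last bin.
* **Staffing presence** — a resource counts as working in a bin when one
  of its event intervals overlaps the bin; no shift roster is assumed.
* **Matching rate** — `1 −` the optimal transportation cost moving the
  log's variant distribution onto the reference model's.  The ground
  distance is the Levenshtein distance between activity sequences divided
  by the longer length, keeping the rate in [0, 1]; the distance function
  is pluggable.  The transportation problem is solved as an
  equality-constrained LP (HiGHS, feasibility tolerances 1e-10); the test
  suite cross-checks it against an exhaustive enumeration of the
  transportation polytope's basic feasible solutions to 1e-9.  The
  reference model is consumed as a stochastic language file (variant,
  probability per row) rather than a Petri net, which keeps the interface
  independent of any particular discovery tool.
* **Triage accuracy** — fraction of cases whose recorded acuity equals a
  classifier's output from the triage vitals; a 5×5 confusion table is
  emitted.  The bundled rule table is a *synthetic placeholder* with
  clinically plausible thresholds (deterministic, most-urgent-first
  evaluation); any official national table must be supplied as JSON.
* **Response rate** — cases with an acuity and a second event are sorted
  by first-event time; an adjacent pair violates when the earlier arrival
  was served later and the acuity comparison holds.  Two readings of the
  comparison exist; the default penalises pairs where the earlier arrival
  has the *greater* acuity number, and a `direction` flag provides the
  alternative (earlier arrival *more* urgent yet served later).  The
  per-period denominator is the number of evaluable cases in the period
  minus one, so a single all-covering period gives the classical
  `1 − violations/(|c|−1)`.
* **Revisit rate** — same-patient case pairs separated by at most the
  window (inclusive), over distinct patients.  Separation is
  start-of-later minus end-of-earlier by default (a revisit means
  returning after leaving); start-to-start is available.

## The synthetic generator

The simulator emulates a full-year tertiary-hospital ER extract, and its
defaults are the package's reference scenario: 30,000
patients over 365 days (~460,000 events, ~15.1 events/case), the 15
canonical ER activities, day-peaked hourly arrivals, KTAS mix
(0.03, 0.15, 0.45, 0.30, 0.07), per-activity exponential service times
with acuity-group multipliers (1.490 / 1.272 / 0.988), admission
probability rising with acuity (0.9 / 0.6 / 0.3), four day-shift and two
night-shift physicians, and a 0.38 % revisit probability.  The service
means and multipliers were calibrated once, analytically, so the implied
closed-form expectations land on the reference scale: mean LOS ≈ 8.35 h
with acuity-group means 11.8 / 8.9 / 6.0 h, admitted ≈ 10.5 h and
discharged ≈ 5.8 h.  Those five group/outcome targets are not jointly
attainable exactly under any single acuity mix with shared service
times — the residual ±8 % on the outcome split is accepted rather than
adding outcome-specific service inflation.

`ground_truth()` returns the exact expectations (LOS moments overall and
by group/terminal, per-activity cycle-time means, variant probabilities,
staffing per hour, revisit rate) computed from the configuration in
closed form; tests compare estimators to these, never to literature
values.  Service draws are rounded to whole seconds with a 1-second
minimum, so clean simulated cases have strictly increasing timestamps and
can never trigger an imperfection remedy — injected artifacts are
therefore exactly recoverable.  Randomness uses one root `SeedSequence`
spawned per patient, so patient *i*'s episode is identical regardless of
the configured patient count and output is byte-identical per seed.

Vitals are sampled per case from safe bands plus one randomly chosen
trigger band, so the rule table maps them to the recorded acuity; with
noise ν the recorded acuity is re-drawn to force disagreement, making the
expected triage accuracy exactly 1 − ν.  The trigger bands are tuned to
the bundled placeholder table, and the sampler verifies each sample
against the supplied table, failing loudly on an incompatible custom
table.  Note that re-labelling also decouples the recorded acuity from
the service-time group, so acuity-stratified LOS on a noised log shrinks
toward the overall mean — visible in the acceptance-script output.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no queueing or congestion (service times are
independent of census, so crowding effects are absent), no day-of-week or
seasonal structure, no left/right-censored episodes, no missing or
malformed fields beyond the four injected patterns, independent acuity
and pathway draws per revisit, and uniform resource assignment within a
shift rather than workload balancing.

## Problem sizes in the test suite

Property tests run on randomly structured logs of up to 200 cases;
parameter-recovery checks use 2,000–5,000 simulated cases (three standard
errors of tolerance against the closed-form expectations); the end-to-end
scale exercise runs the full sixteen-indicator report on a complete
default scenario (~30,000 cases).  The acceptance script uses 5,000
patients over 60 days, enough for sub-percent sampling error on the
headline means while keeping the run short.

## Known limitations

* Stay lengths are treated as complete; no survival treatment of episodes
  truncated by the extraction window.
* The staffing-cost proxy (distinct originators) assumes full-time
  resources; no salary or overhead modelling.
* Process-model discovery and alignment-based fitness are out of scope;
  the matching rate requires an externally supplied reference language.
* The rule-table classifier is intentionally a placeholder; triage
  accuracy on real data is only meaningful with the applicable official
  rule set.
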