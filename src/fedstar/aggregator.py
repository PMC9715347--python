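"""Aggregator: owns the global model and drives synchronous federated rounds.

One round proceeds as: every roster collaborator asks for its tasks
(assigned exactly once per round), trains locally, and submits tensors plus
metrics. The round closes when either everyone has reported, or the round
cutoff has elapsed and at least the quorum ``ceil(min_reporting_fraction x
roster)`` has reported. At close, the plan's aggregation method combines
the received updates — weighted by each site's declared dataset size — into
the consensus model for that round. Late submissions are acknowledged and
discarded, never merged retroactively; duplicate submissions keep the first
and log the second as potential misbehavior; a cutoff with fewer reports
than quorum halts the federation loudly rather than degrading silently.

The clock is injected (an abstract float) so straggler scenarios are
unit-testable without timers. Every protocol action is journaled; replaying
a journal into a fresh aggregator reproduces the same tensor store
bit-for-bit.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

from .aggregation import DEFAULT_REGISTRY, MetricReport, WeightedUpdate, aggregate_metric
from .errors import AuthorizationError, FederationHalt
from .tensors import INITIAL_ROUND, TensorKey, flatten_model

#: sentinel results from next_tasks
FINISHED = "finished"
WAIT = "wait"

#: how many closed rounds of tensors to retain (current + previous)
RETENTION_HORIZON = 2


@dataclass
class TaskAssignment:
    round_num: int
    tasks: list
    global_tensors_ref: int  # round whose consensus to fetch; -1 = initial model


@dataclass
class ResultsSubmission:
    origin: str
    round_num: int
    tensors: list  # NamedTensor, tag {trained}; empty for validate-only
    metrics: list  # MetricReport
    declared_size: int

    def __post_init__(self):
        if self.declared_size < 1:
            raise ValueError("declared_size must be a positive integer")


@dataclass
class RoundState:
    round_num: int
    expected: set
    opened_at: float
    received: set = field(default_factory=set)
    assigned: set = field(default_factory=set)
    status: str = "open"


class Aggregator:
    """Server-side federation state machine (transport-agnostic)."""

    def __init__(self, plan, initial_model, registry=None, clock0=0.0):
        self.plan = plan
        self.registry = registry or DEFAULT_REGISTRY
        self._method = self.registry.resolve(plan.aggregation.method)
        self.initial_model = {k: v.copy() for k, v in initial_model.items()}
        self.store = {}  # TensorKey -> NamedTensor
        self.metrics_rows = []  # (round, metric, value, n_reporting)
        self.events = []  # structured protocol journal
        self.round = RoundState(0, set(plan.collaborators), opened_at=clock0)
        self.closed_rounds = 0
        self.finished = False
        self._submissions = {}  # (round, origin) -> ResultsSubmission (open round only)

    # -- helpers ----------------------------------------------------------

    def _log(self, event, origin=None, clock=None, **extra):
        self.events.append(
            {"event": event, "round": self.round.round_num if not self.finished else self.closed_rounds,
             "origin": origin, "clock": clock, **extra}
        )

    def quorum(self):
        return self.plan.quorum()

    # -- protocol operations ----------------------------------------------

    def next_tasks(self, collab, clock=None):
        """Assign the plan's task list for the open round, once per
        (collaborator, round); WAIT if already assigned, FINISHED when done."""
        if collab not in self.plan.collaborators:
            self._log("authz_reject", origin=collab, clock=clock)
            raise AuthorizationError(f"{collab!r} is not in the plan roster")
        if self.finished:
            self._log("finished_signal", origin=collab, clock=clock)
            return FINISHED
        r = self.round
        if collab in r.assigned or collab in r.received:
            self._log("wait_signal", origin=collab, clock=clock)
            return WAIT
        r.assigned.add(collab)
        self._log("assign", origin=collab, clock=clock)
        return TaskAssignment(
            round_num=r.round_num,
            tasks=list(self.plan.tasks),
            global_tensors_ref=r.round_num - 1,
        )

    def accept_results(self, sub: ResultsSubmission, clock=None):
        """Store a submission for the open round; returns an ack status string:
        'stored', 'discarded_late', or 'rejected_duplicate'."""
        if sub.origin not in self.plan.collaborators:
            self._log("authz_reject", origin=sub.origin, clock=clock)
            raise AuthorizationError(f"{sub.origin!r} is not in the plan roster")
        if self.finished or sub.round_num < self.round.round_num:
            self._log("late_discard", origin=sub.origin, clock=clock, sub_round=sub.round_num)
            return "discarded_late"
        r = self.round
        if sub.round_num != r.round_num:
            raise ValueError(
                f"submission for future round {sub.round_num} (open round is {r.round_num})"
            )
        if sub.origin in r.received:
            self._log("duplicate_reject", origin=sub.origin, clock=clock)
            return "rejected_duplicate"
        if sub.origin not in r.assigned:
            raise AuthorizationError(
                f"{sub.origin!r} submitted for round {r.round_num} without an assignment"
            )
        template = self.initial_model
        for t in sub.tensors:
            if t.key.name not in template:
                raise ValueError(f"unknown model entry {t.key.name!r} in submission")
            if t.declared_shape != tuple(template[t.key.name].shape):
                raise ValueError(
                    f"shape mismatch for {t.key.name!r} from {sub.origin}: "
                    f"{t.declared_shape} vs {tuple(template[t.key.name].shape)}"
                )
        if self.plan.train_tasks() and not sub.tensors:
            raise ValueError("train tasks assigned but submission carries no tensors")
        for t in sub.tensors:
            key = TensorKey(t.key.name, sub.origin, r.round_num, frozenset({"trained"}))
            self.store[key] = type(t)(key, t.values)
        r.received.add(sub.origin)
        self._submissions[(r.round_num, sub.origin)] = sub
        self._log("accept", origin=sub.origin, clock=clock, n_tensors=len(sub.tensors))
        return "stored"

    def close_round_if_ready(self, now):
        """Close the open round if the full roster or the quorum-at-cutoff
        condition is met; returns the consensus ModelState or None."""
        if self.finished:
            return None
        r = self.round
        full = r.received == r.expected
        cutoff = now - r.opened_at >= self.plan.straggler.round_cutoff
        if not full and not cutoff:
            return None
        if not full:
            if len(r.received) < self.quorum():
                self._log("halt", clock=now, received=sorted(r.received))
                raise FederationHalt(r.round_num, len(r.received), self.quorum())
            self._log("quorum_close", clock=now, received=sorted(r.received))
        return self._close(now)

    def _close(self, now):
        r = self.round
        subs = [self._submissions[(r.round_num, o)] for o in sorted(r.received)]
        consensus = {}
        for name, template in self.initial_model.items():
            group = []
            for sub in subs:
                for t in sub.tensors:
                    if t.key.name == name:
                        group.append(WeightedUpdate(t, float(sub.declared_size)))
            agg = self._method(group, r.round_num)
            if agg.declared_shape != tuple(template.shape):
                raise ValueError(
                    f"aggregation method returned shape {agg.declared_shape} "
                    f"for {name!r}, expected {tuple(template.shape)}"
                )
            key = TensorKey(name, "aggregator", r.round_num, frozenset({"aggregated"}))
            self.store[key] = type(agg)(key, agg.values)
            consensus[name] = agg.values.copy()

        by_metric = {}
        for sub in subs:
            for m in sub.metrics:
                by_metric.setdefault(m.name, []).append(m)
        for mname in sorted(by_metric):
            reports = by_metric[mname]
            self.metrics_rows.append(
                (r.round_num, mname, aggregate_metric(reports), len(reports))
            )

        self._log("close", clock=now, n_received=len(r.received))
        r.status = "closed"
        self.closed_rounds += 1
        self._prune(r.round_num)
        self._submissions = {
            k: v for k, v in self._submissions.items() if k[0] > r.round_num
        }
        if self.closed_rounds >= self.plan.rounds_to_train:
            self.finished = True
        else:
            self.round = RoundState(
                r.round_num + 1, set(self.plan.collaborators), opened_at=now
            )
        return consensus

    def _prune(self, closed_round):
        horizon = closed_round - RETENTION_HORIZON
        if horizon < 0:
            return
        stale = [k for k in self.store if k.round_num <= horizon]
        for k in stale:
            del self.store[k]

    def get_global_tensors(self, round_num):
        """Aggregated tensors for a closed round; -1 means the initial model.
        Returns None (not-ready) for open or unknown rounds."""
        if round_num == INITIAL_ROUND:
            return flatten_model(
                self.initial_model, "aggregator", INITIAL_ROUND, {"aggregated"}
            )
        tensors = [
            self.store[k]
            for k in sorted(self.store, key=lambda k: k.name)
            if k.round_num == round_num and "aggregated" in k.tags
        ]
        if not tensors:
            return None
        order = {n: i for i, n in enumerate(self.initial_model)}
        tensors.sort(key=lambda t: order[t.key.name])
        return tensors

    # -- reporting ----------------------------------------------------------

    def event_log_lines(self):
        """Structured JSON-lines protocol log (metadata only)."""
        keep = ("event", "round", "origin", "clock")
        return [json.dumps({k: e.get(k) for k in keep}) for e in self.events]

    def write_event_log(self, path):
        with open(path, "w") as fh:
            fh.write("\n".join(self.event_log_lines()) + "\n")

    def write_metrics_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["round", "metric", "value", "n_reporting"])
            w.writerows(self.metrics_rows)


def replay_journal(plan, initial_model, actions, registry=None):
    """Re-apply a recorded action sequence to a fresh aggregator.

    *actions* is a list of ("next_tasks", collab, clock) /
    ("accept_results", submission, clock) / ("close", clock) tuples, as a
    driver would record them. Used to verify the aggregator is a pure
    function of its input event sequence.
    """
    agg = Aggregator(plan, initial_model, registry=registry)
    for action in actions:
        kind = action[0]
        if kind == "next_tasks":
            agg.next_tasks(action[1], clock=action[2])
        elif kind == "accept_results":
            agg.accept_results(action[1], clock=action[2])
        elif kind == "close":
            agg.close_round_if_ready(action[1])
        else:
            raise ValueError(f"unknown journal action {kind!r}")
    return agg
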