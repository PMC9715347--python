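"""Aggregator state machine: assignment, quorum, round close, replay."""

import numpy as np
import pytest

from conftest import make_plan

from fedstar.aggregation import MetricReport
from fedstar.aggregator import (
    FINISHED,
    WAIT,
    Aggregator,
    ResultsSubmission,
    TaskAssignment,
    replay_journal,
)
from fedstar.errors import AuthorizationError, FederationHalt
from fedstar.tensors import flatten_model


def _model():
    return {"w": np.zeros(3, np.float32), "b": np.zeros((), np.float32)}


def _submission(origin, round_num, value, size=10):
    state = {"w": np.full(3, value, np.float32), "b": np.array(value, np.float32)}
    return ResultsSubmission(
        origin=origin,
        round_num=round_num,
        tensors=flatten_model(state, origin, round_num, {"trained"}),
        metrics=[MetricReport("accuracy", 0.5 + value / 100, size)],
        declared_size=size,
    )


@pytest.fixture
def agg():
    return Aggregator(make_plan(rounds=2, cutoff=100.0, min_fraction=0.5), _model())


class TestAssignment:
    def test_fresh_federation_assigns_round_zero(self, agg):
        a = agg.next_tasks("site_a")
        assert isinstance(a, TaskAssignment)
        assert a.round_num == 0
        assert a.tasks == ["train", "validate"]
        assert a.global_tensors_ref == -1

    def test_second_ask_waits(self, agg):
        agg.next_tasks("site_a")
        assert agg.next_tasks("site_a") == WAIT

    def test_unknown_collaborator_rejected(self, agg):
        with pytest.raises(AuthorizationError):
            agg.next_tasks("intruder")

    def test_finished_after_all_rounds(self, agg):
        for r in range(2):
            for c in ("site_a", "site_b", "site_c"):
                agg.next_tasks(c)
                agg.accept_results(_submission(c, r, 1.0))
            agg.close_round_if_ready(now=0.0)
        assert agg.next_tasks("site_a") == FINISHED


class TestSubmissions:
    def test_store_and_received_updated(self, agg):
        agg.next_tasks("site_b")
        assert agg.accept_results(_submission("site_b", 0, 2.0)) == "stored"
        assert agg.round.received == {"site_b"}

    def test_duplicate_first_wins(self, agg):
        agg.next_tasks("site_b")
        agg.accept_results(_submission("site_b", 0, 2.0))
        before = {k: t.values.copy() for k, t in agg.store.items()}
        assert agg.accept_results(_submission("site_b", 0, 99.0)) == "rejected_duplicate"
        for k, t in agg.store.items():
            assert np.array_equal(t.values, before[k])

    def test_late_submission_discarded(self, agg):
        for c in ("site_a", "site_b"):
            agg.next_tasks(c)
            agg.accept_results(_submission(c, 0, 1.0))
        agg.next_tasks("site_c")
        agg.close_round_if_ready(now=200.0)  # quorum close without site_c
        n_keys = len(agg.store)
        assert agg.accept_results(_submission("site_c", 0, 5.0)) == "discarded_late"
        assert len(agg.store) == n_keys

    def test_shape_mismatch_rejected(self, agg):
        agg.next_tasks("site_a")
        bad_state = {"w": np.zeros(4, np.float32), "b": np.zeros((), np.float32)}
        sub = ResultsSubmission(
            "site_a", 0, flatten_model(bad_state, "site_a", 0, {"trained"}), [], 10
        )
        with pytest.raises(ValueError, match="shape mismatch"):
            agg.accept_results(sub)

    def test_submission_without_assignment_rejected(self, agg):
        with pytest.raises(AuthorizationError, match="assignment"):
            agg.accept_results(_submission("site_a", 0, 1.0))


class TestRoundClose:
    def test_full_participation_closes_immediately(self, agg):
        sizes = {"site_a": 10, "site_b": 30, "site_c": 60}
        for c, s in sizes.items():
            agg.next_tasks(c)
            agg.accept_results(_submission(c, 0, {"site_a": 1, "site_b": 3, "site_c": 5}[c], s))
        consensus = agg.close_round_if_ready(now=0.0)
        expect = (1 * 10 + 3 * 30 + 5 * 60) / 100
        assert np.allclose(consensus["w"], expect)
        assert agg.round.round_num == 1

    def test_stays_open_before_cutoff(self, agg):
        for c in ("site_a", "site_b"):
            agg.next_tasks(c)
            agg.accept_results(_submission(c, 0, 1.0))
        assert agg.close_round_if_ready(now=50.0) is None
        assert agg.round.round_num == 0

    def test_quorum_close_at_cutoff_discards_straggler(self, agg):
        for c in ("site_a", "site_b"):
            agg.next_tasks(c)
            agg.accept_results(_submission(c, 0, 2.0))
        consensus = agg.close_round_if_ready(now=100.0)
        assert consensus is not None
        assert agg.accept_results(_submission("site_c", 0, 9.0)) == "discarded_late"
        # consensus unaffected by the late value
        stored = agg.get_global_tensors(0)
        assert np.allclose(stored[0].values, 2.0)

    def test_below_quorum_at_cutoff_halts(self):
        plan = make_plan(rounds=2, cutoff=10.0, min_fraction=0.7)  # quorum = 3
        agg = Aggregator(plan, _model())
        agg.next_tasks("site_a")
        agg.accept_results(_submission("site_a", 0, 1.0))
        with pytest.raises(FederationHalt):
            agg.close_round_if_ready(now=10.0)

    def test_metrics_aggregated_per_round(self, agg):
        for c, v in (("site_a", 2.0), ("site_b", 4.0), ("site_c", 6.0)):
            agg.next_tasks(c)
            agg.accept_results(_submission(c, 0, v, size=10))
        agg.close_round_if_ready(now=0.0)
        rows = [r for r in agg.metrics_rows if r[1] == "accuracy"]
        assert len(rows) == 1
        assert rows[0][0] == 0 and rows[0][3] == 3
        assert rows[0][2] == pytest.approx(np.mean([0.52, 0.54, 0.56]))


class TestGlobalTensors:
    def test_initial_model_at_minus_one(self, agg):
        tensors = agg.get_global_tensors(-1)
        assert [t.key.name for t in tensors] == ["w", "b"]
        assert all("aggregated" in t.key.tags for t in tensors)

    def test_open_round_not_ready(self, agg):
        assert agg.get_global_tensors(0) is None
        assert agg.get_global_tensors(7) is None

    def test_closed_round_matches_aggregation(self, agg):
        for c in ("site_a", "site_b", "site_c"):
            agg.next_tasks(c)
            agg.accept_results(_submission(c, 0, 3.0))
        consensus = agg.close_round_if_ready(now=0.0)
        stored = agg.get_global_tensors(0)
        assert np.array_equal(stored[0].values, consensus["w"])

    def test_retention_horizon_prunes_old_rounds(self):
        plan = make_plan(rounds=5, collaborators=["solo"])
        agg = Aggregator(plan, _model())
        for r in range(5):
            agg.next_tasks("solo")
            agg.accept_results(_submission("solo", r, float(r)))
            agg.close_round_if_ready(now=0.0)
        assert agg.get_global_tensors(0) is None  # pruned
        assert agg.get_global_tensors(4) is not None


class TestJournal:
    def test_replay_reproduces_tensor_store(self):
        plan = make_plan(rounds=2, cutoff=100.0, min_fraction=0.5)
        agg = Aggregator(plan, _model())
        actions = []

        def do(kind, *args):
            actions.append((kind, *args))
            if kind == "next_tasks":
                agg.next_tasks(args[0], clock=args[1])
            elif kind == "accept_results":
                agg.accept_results(args[0], clock=args[1])
            else:
                agg.close_round_if_ready(args[0])

        for r in range(2):
            for i, c in enumerate(("site_a", "site_b", "site_c")):
                do("next_tasks", c, float(r * 10 + i))
                do("accept_results", _submission(c, r, float(r + i)), float(r * 10 + i))
            do("close", float(r * 10 + 9))

        replayed = replay_journal(plan, _model(), actions)
        assert set(replayed.store) == set(agg.store)
        for k in agg.store:
            assert np.array_equal(replayed.store[k].values, agg.store[k].values)

    def test_event_log_lines_schema(self, agg):
        agg.next_tasks("site_a", clock=1.0)
        import json

        line = json.loads(agg.event_log_lines()[0])
        assert set(line) == {"event", "round", "origin", "clock"}
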