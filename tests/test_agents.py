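"""Agent-runtime tests: subscriptions, availability gating, the analyser's
prediction/retraining split, planner polling and executor back-pressure."""

import itertools
from datetime import timedelta

import numpy as np
import pytest

from driftmon.adwin import AdwinDetector
from driftmon.agents import (
    AgentDescriptor,
    Alert,
    AnalyserAgent,
    ExecutorAgent,
    ListSink,
    LogicalClock,
    MonitorAgent,
    PlannerAgent,
    Registry,
    Sample,
)
from driftmon.delta import DeltaController
from driftmon.kb import InMemoryKnowledgeBase

from conftest import EPOCH, make_record


def sample(identifier="left_thigh", value=0.0, t=0):
    return Sample(
        identifier=identifier,
        value=value,
        timestamp_ms=t,
        monitored_at=EPOCH + timedelta(milliseconds=t),
    )


def make_analyser(kb, jid="analyser_left_thigh", identifier="left_thigh",
                  registry=None, chunk_size=2000, calibration_n=0, delta=0.01):
    return AnalyserAgent(
        jid=jid,
        identifier=identifier,
        detector=AdwinDetector(delta=delta),
        controller=DeltaController(start=delta, chunk_size=chunk_size),
        kb=kb,
        clock=LogicalClock(EPOCH),
        registry=registry,
        calibration_n=calibration_n,
    )


class TestSubscriptions:
    def test_fresh_subscription_is_reciprocal(self):
        reg = Registry()
        reg.register(AgentDescriptor("M1", "monitor"))
        reg.register(AgentDescriptor("A1", "analyser"))
        reg.subscribe("A1", "M1")
        assert reg.subscribers_of("M1") == ["A1"]
        assert reg.subscribers_of("A1") == ["M1"]

    def test_duplicate_subscribe_is_idempotent(self):
        reg = Registry()
        reg.register(AgentDescriptor("M1", "monitor"))
        reg.register(AgentDescriptor("A1", "analyser"))
        reg.subscribe("A1", "M1")
        reg.subscribe("A1", "M1")
        assert reg.subscribers_of("M1") == ["A1"]
        assert len(reg.subscriptions) == 2

    def test_subscribe_to_unregistered_agent_leaves_registry_unchanged(self):
        reg = Registry()
        reg.register(AgentDescriptor("A1", "analyser"))
        with pytest.raises(KeyError):
            reg.subscribe("A1", "ghost_monitor")
        assert reg.subscriptions == set()

    def test_duplicate_jid_rejected(self):
        reg = Registry()
        reg.register(AgentDescriptor("A1", "analyser"))
        with pytest.raises(ValueError):
            reg.register(AgentDescriptor("A1", "monitor"))


class TestMonitorEmit:
    @pytest.mark.parametrize("n_subs", [1, 2, 3])
    def test_delivery_matches_every_availability_combination(self, n_subs):
        for availability in itertools.product([True, False], repeat=n_subs):
            reg = Registry()
            monitor = MonitorAgent("M1", reg)
            for i in range(n_subs):
                reg.register(AgentDescriptor(f"A{i}", "analyser", availability[i]))
                reg.subscribe(f"A{i}", "M1")
            delivered = monitor.emit(sample())
            expected = [f"A{i}" for i in range(n_subs) if availability[i]]
            assert delivered == expected

    def test_unavailable_subscriber_drop_is_counted(self):
        reg = Registry()
        monitor = MonitorAgent("M1", reg)
        reg.register(AgentDescriptor("A1", "analyser", available=False))
        reg.subscribe("A1", "M1")
        assert monitor.emit(sample()) == []
        assert monitor.dropped == 1


class TestAnalyser:
    def test_constant_sample_persists_a_negative_record(self):
        kb = InMemoryKnowledgeBase()
        analyser = make_analyser(kb)
        record = analyser.handle(sample(value=5.0))
        assert record is not None and record.predicted is False
        assert record.jid == analyser.jid
        assert record.identifier == "left_thigh"
        assert record.data == {"sensor": 5.0}
        assert kb.count() == 1

    def test_detectable_shift_yields_positive_record(self, rng):
        kb = InMemoryKnowledgeBase()
        analyser = make_analyser(kb)
        stream = np.concatenate([rng.normal(0, 1, 300), rng.normal(10, 1, 50)])
        records = [
            analyser.handle(sample(value=v, t=i)) for i, v in enumerate(stream)
        ]
        assert any(r.predicted for r in records if r is not None)
        assert kb.count() == len(stream)  # one record per delivered sample

    def test_non_finite_sample_skipped_with_nothing_persisted(self):
        kb = InMemoryKnowledgeBase()
        analyser = make_analyser(kb)
        assert analyser.handle(sample(value=float("nan"))) is None
        assert kb.count() == 0
        assert analyser.skipped == 1

    def test_retrain_fires_exactly_at_chunk_boundaries(self):
        kb = InMemoryKnowledgeBase()
        analyser = make_analyser(kb, chunk_size=100)
        deltas = []
        for i in range(250):
            analyser.handle(sample(value=0.0, t=i))
            analyser.retrain_if_due()
            deltas.append(analyser.detector.delta)
        assert analyser.counters["retrain_calls"] == 2
        # constant stream: rate stays 0, delta stays at its start everywhere
        assert set(deltas) == {0.01}

    def test_published_delta_changes_only_at_chunk_boundaries(self, rng):
        kb = InMemoryKnowledgeBase()
        analyser = make_analyser(kb, chunk_size=100, delta=1.0)
        stream = np.concatenate(
            [rng.normal(0, 1, 100), rng.normal(12, 1, 100), rng.normal(12, 1, 100)]
        )
        per_sample = []
        for i, v in enumerate(stream):
            analyser.handle(sample(value=v, t=i))
            per_sample.append(analyser.detector.delta)
            analyser.retrain_if_due()
        changes = {
            i + 1 for i, (a, b) in enumerate(zip(per_sample, per_sample[1:])) if a != b
        }
        assert changes <= {100, 200, 300}
        assert changes  # the shift made the rate rise, so delta did move

    def test_no_training_computation_inside_predict_path(self, rng):
        kb = InMemoryKnowledgeBase()
        analyser = make_analyser(kb, chunk_size=50)
        for i, v in enumerate(rng.normal(0, 1, 200)):
            analyser.handle(sample(value=v, t=i))
            analyser.retrain_if_due()
        assert analyser.counters["training_ops_in_predict"] == 0
        assert analyser.counters["retrain_calls"] == 4


class TestPlannerPolling:
    @staticmethod
    def planner(kb):
        return PlannerAgent(kb, lambda s, e, recs: None, origin=EPOCH)

    def test_empty_kb_polls_nothing(self):
        assert self.planner(InMemoryKnowledgeBase()).poll() == []

    def test_all_records_polled_once(self):
        kb = InMemoryKnowledgeBase()
        for i in range(3):
            kb.insert_prediction(make_record(monitored_ms=i))
        planner = self.planner(kb)
        assert len(planner.poll()) == 3
        assert planner.poll() == []

    def test_second_poll_sees_exactly_the_new_records(self):
        kb = InMemoryKnowledgeBase()
        planner = self.planner(kb)
        kb.insert_prediction(make_record(monitored_ms=0))
        planner.poll()
        fresh = [make_record(monitored_ms=10), make_record(monitored_ms=11)]
        for r in fresh:
            kb.insert_prediction(r)
        assert planner.poll() == [r.normalised() for r in fresh]


class TestExecutor:
    @staticmethod
    def alert(i):
        return Alert(
            window_start_ms=1000 * i,
            window_end_ms=1000 * (i + 1),
            n_drift=2,
            identifiers=("left_hamstring", "left_thigh"),
            decided_at=EPOCH + timedelta(seconds=i + 1),
        )

    def test_live_sink_delivers(self):
        executor = ExecutorAgent(ListSink())
        assert executor.deliver(self.alert(0)) == "delivered"
        assert len(executor.sink.items) == 1

    def test_dead_sink_holds_and_planner_is_informed(self):
        executor = ExecutorAgent(ListSink(alive=False))
        assert executor.deliver(self.alert(0)) == "held"
        assert executor.accepting is False
        assert executor.held

    def test_recovery_preserves_total_order(self):
        sink = ListSink()
        executor = ExecutorAgent(sink)
        statuses = []
        for i in range(5):
            if i == 2:
                sink.alive = False
            if i == 4:
                sink.alive = True
            statuses.append(executor.deliver(self.alert(i)))
        executor.pump()
        assert statuses == ["delivered", "delivered", "held", "held", "delivered"]
        assert [a.window_start_ms for a in sink.items] == [0, 1000, 2000, 3000, 4000]


class TestEndToEndConservation:
    def test_every_delivered_sample_yields_exactly_one_record(self, rng):
        reg = Registry()
        kb = InMemoryKnowledgeBase()
        monitor = MonitorAgent("M1", reg)
        analyser = make_analyser(kb, registry=reg)
        reg.subscribe(analyser.jid, "M1")
        emitted = delivered = 0
        for i, v in enumerate(rng.normal(0, 1, 500)):
            if i == 200:
                reg.set_available(analyser.jid, False)
            if i == 300:
                reg.set_available(analyser.jid, True)
            emitted += 1
            for jid in monitor.emit(sample(value=v, t=i)):
                analyser.handle(sample(value=v, t=i))
                delivered += 1
        assert emitted == 500
        assert delivered == 400  # 100 samples dropped while unavailable
        assert kb.count() == delivered
        assert monitor.dropped == 100

    def test_all_analysers_unavailable_means_empty_kb(self):
        reg = Registry()
        kb = InMemoryKnowledgeBase()
        monitor = MonitorAgent("M1", reg)
        analyser = make_analyser(kb, registry=reg)
        reg.subscribe(analyser.jid, "M1")
        reg.set_available(analyser.jid, False)
        for i in range(100):
            for jid in monitor.emit(sample(t=i)):
                analyser.handle(sample(t=i))
        assert kb.count() == 0
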