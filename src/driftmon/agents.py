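"""MAPE-K agent roles over an in-process message bus.

Four roles cooperate through a shared knowledge base:

* **Monitor** — captures samples for one channel and forwards each one to
  every subscribed analyser that is currently available (no buffering: a
  sample for an unavailable analyser is dropped, and the drop is logged).
* **Analyser** — runs the drift detector on each delivered sample and
  persists exactly one prediction record to the knowledge base; a separate
  retraining task re-regulates the detector confidence delta.  The
  prediction path never executes training computation — the published delta
  changes only between predictions, at chunk boundaries.
* **Planner** — polls the knowledge base for new predictions and decides,
  per tumbling decision window, whether an alert should be raised.
* **Executor** — delivers alerts to a sink, holding them (and informing the
  planner) while the sink is down; held alerts drain in order on recovery.

Subscriptions are reciprocal: a monitor also tracks its analysers'
availability because it must know whether they can receive new data.  The
transport here is an in-process synchronous bus behind these interfaces;
any message-oriented transport with the same subscription/availability/
back-pressure semantics can replace it.

Every noteworthy event (emit, deliver, drop, predict, retrain, poll, alert,
hold) is logged as one JSON object on the ``driftmon`` logger.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Callable, Dict, List, Optional, Protocol, Sequence, Tuple

import numpy as np

from .adwin import AdwinDetector
from .delta import DeltaController
from .kb import KnowledgeBase, PredictionRecord

__all__ = [
    "Sample",
    "AgentDescriptor",
    "Subscription",
    "Registry",
    "LogicalClock",
    "MonitorAgent",
    "AnalyserAgent",
    "PlannerAgent",
    "ExecutorAgent",
    "ListSink",
    "ROLES",
]

logger = logging.getLogger("driftmon")

ROLES = ("monitor", "analyser", "planner", "executor")


def _log(event: str, **fields) -> None:
    if logger.isEnabledFor(logging.INFO):
        logger.info(json.dumps({"event": event, **fields}, default=str))


@dataclass(frozen=True)
class Sample:
    """One timestamped sensor reading for one named channel (muscle)."""

    identifier: str
    value: float
    timestamp_ms: int
    monitored_at: datetime

    def __post_init__(self):
        if not self.identifier:
            raise ValueError("identifier must be non-empty")
        if self.timestamp_ms < 0:
            raise ValueError(f"timestamp_ms must be >= 0, got {self.timestamp_ms}")


@dataclass
class AgentDescriptor:
    jid: str
    role: str
    available: bool = True

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


@dataclass(frozen=True)
class Subscription:
    subscriber: str
    publisher: str
    reciprocal: bool = True


class Registry:
    """Agent directory plus the subscription table of the message bus."""

    def __init__(self) -> None:
        self.agents: Dict[str, AgentDescriptor] = {}
        self.subscriptions: set[Subscription] = set()

    def register(self, descriptor: AgentDescriptor) -> None:
        if descriptor.jid in self.agents:
            raise ValueError(f"jid already registered: {descriptor.jid}")
        self.agents[descriptor.jid] = descriptor

    def set_available(self, jid: str, available: bool) -> None:
        self._require(jid).available = available

    def is_available(self, jid: str) -> bool:
        return self._require(jid).available

    def _require(self, jid: str) -> AgentDescriptor:
        try:
            return self.agents[jid]
        except KeyError:
            raise KeyError(f"unknown agent jid: {jid}") from None

    def subscribe(self, analyser_jid: str, monitor_jid: str) -> None:
        """Record the reciprocal monitor<->analyser link (idempotent).

        The analyser subscribes to the monitor to receive its data; the
        monitor subscribes back so it knows whether the analyser is up.
        """
        self._require(analyser_jid)
        self._require(monitor_jid)
        self.subscriptions.add(Subscription(analyser_jid, monitor_jid))
        self.subscriptions.add(Subscription(monitor_jid, analyser_jid))

    def subscribers_of(self, publisher_jid: str) -> List[str]:
        subs = sorted(
            s.subscriber for s in self.subscriptions if s.publisher == publisher_jid
        )
        return subs


class LogicalClock:
    """Deterministic clock the pipeline advances in stream time."""

    def __init__(self, start: datetime) -> None:
        self._now = start

    def now(self) -> datetime:
        return self._now

    def advance_to(self, when: datetime) -> None:
        self._now = max(self._now, when)


class MonitorAgent:
    """Captures data for one channel and fans it out to available analysers."""

    def __init__(self, jid: str, registry: Registry) -> None:
        self.jid = jid
        self.registry = registry
        self.dropped = 0
        if jid not in registry.agents:
            registry.register(AgentDescriptor(jid=jid, role="monitor"))

    def emit(self, sample: Sample) -> List[str]:
        """Deliver `sample` to each subscribed *available* analyser.

        Returns the jids actually delivered to; drops (analyser down) are
        counted and logged, never buffered.
        """
        delivered = []
        for sub in self.registry.subscribers_of(self.jid):
            if self.registry.agents[sub].role != "analyser":
                continue
            if self.registry.is_available(sub):
                delivered.append(sub)
            else:
                self.dropped += 1
                _log("drop", monitor=self.jid, analyser=sub,
                     identifier=sample.identifier, timestamp_ms=sample.timestamp_ms)
        _log("emit", monitor=self.jid, identifier=sample.identifier,
             timestamp_ms=sample.timestamp_ms, delivered=len(delivered))
        return delivered


class AnalyserAgent:
    """Per-channel drift analyser with an asynchronous retraining contract.

    The prediction path (:meth:`handle`) only runs the detector and persists
    one record; delta retraining (:meth:`retrain_if_due`) is a separate task
    that reads the channel's recent history from the knowledge base, updates
    the controller counters with the drift verdicts recorded there, and
    publishes the new delta to the detector between predictions.  The
    instrumentation counter ``training_ops_in_predict`` stays at zero over
    any run — the testable form of the training/prediction decoupling.

    An optional calibration prefix (``calibration_n`` samples) estimates the
    channel scale before detection starts: the variance-adaptive threshold's
    range term expects order-one values, while raw EMG is in the hundreds of
    microvolts.  Calibration samples are still persisted (predicted=false).
    """

    def __init__(
        self,
        jid: str,
        identifier: str,
        detector: AdwinDetector,
        controller: DeltaController,
        kb: KnowledgeBase,
        clock: Optional[LogicalClock] = None,
        registry: Optional[Registry] = None,
        calibration_n: int = 0,
    ) -> None:
        self.jid = jid
        self.identifier = identifier
        self.detector = detector
        self.controller = controller
        self.kb = kb
        self.clock = clock
        self.calibration_n = int(calibration_n)
        self.scale = 1.0
        self._calibration_buf: list[float] = []
        self.samples_handled = 0
        self.samples_since_retrain = 0
        self.skipped = 0
        self.counters = {
            "predict_calls": 0,
            "training_ops_in_predict": 0,
            "retrain_calls": 0,
        }
        self._in_predict = False
        detector.delta = controller.delta  # the controller owns delta
        if registry is not None and jid not in registry.agents:
            registry.register(AgentDescriptor(jid=jid, role="analyser"))

    def _now(self) -> datetime:
        return self.clock.now() if self.clock is not None else datetime.now()

    @property
    def calibrating(self) -> bool:
        return self.samples_handled < self.calibration_n

    def handle(self, sample: Sample) -> Optional[PredictionRecord]:
        """Predict on one sample and persist exactly one record.

        Non-finite values are skipped with a diagnostic naming the channel
        and timestamp; nothing is persisted for them.  A failed KB write is
        retried once, then surfaced.
        """
        self.counters["predict_calls"] += 1
        self._in_predict = True
        try:
            if not math.isfinite(sample.value):
                self.skipped += 1
                _log("skip", analyser=self.jid, identifier=sample.identifier,
                     timestamp_ms=sample.timestamp_ms,
                     reason=f"non-finite value {sample.value!r}")
                return None
            if self.calibrating:
                self._calibration_buf.append(float(sample.value))
                predicted = False
                if len(self._calibration_buf) == self.calibration_n:
                    s = float(np.std(self._calibration_buf))
                    self.scale = s if s > 0.0 else 1.0
                    self._calibration_buf.clear()
                    _log("calibrated", analyser=self.jid, scale=self.scale)
            else:
                try:
                    predicted = self.detector.update(sample.value / self.scale)
                except ValueError as exc:
                    self.skipped += 1
                    _log("skip", analyser=self.jid, identifier=sample.identifier,
                         timestamp_ms=sample.timestamp_ms, reason=str(exc))
                    return None
            record = PredictionRecord(
                jid=self.jid,
                data={"sensor": sample.value},
                datetime_monitored=sample.monitored_at,
                # analysis cannot precede capture even if the clock lags
                datetime_analysed=max(self._now(), sample.monitored_at),
                identifier=sample.identifier,
                predicted=predicted,
            )
            try:
                self.kb.insert_prediction(record)
            except Exception:
                self.kb.insert_prediction(record)  # one retry, then surface
            self.samples_handled += 1
            self.samples_since_retrain += 1
            _log("predict", analyser=self.jid, identifier=sample.identifier,
                 timestamp_ms=sample.timestamp_ms, predicted=predicted)
            return record
        finally:
            self._in_predict = False

    def retrain_if_due(self) -> Optional[float]:
        """Run one delta training step if a full chunk has accumulated.

        Queries the channel's newest chunk of records from the knowledge
        base, counts the drift verdicts stored there into the controller,
        and applies one decade step; the new delta is published to the
        detector atomically between predictions.  Returns the new delta, or
        None if not due.
        """
        if self._in_predict:
            # contract violation: training computation inside the predict path
            self.counters["training_ops_in_predict"] += 1
        chunk = self.controller.chunk_size
        if self.samples_since_retrain < chunk:
            return None
        records = self.kb.query_training(self.identifier, chunk)
        n_drifts = sum(1 for r in records if r.predicted)
        self.controller.absorb(len(records), n_drifts)
        self.controller.end_chunk()
        self.detector.delta = self.controller.delta
        self.samples_since_retrain = 0
        self.counters["retrain_calls"] += 1
        _log("retrain", analyser=self.jid, delta=self.controller.delta,
             rate=self.controller.drift_rate())
        return self.controller.delta


@dataclass(frozen=True)
class Alert:
    """A planner decision: which channels drifted within one decision window."""

    window_start_ms: int
    window_end_ms: int
    n_drift: int
    identifiers: Tuple[str, ...]
    decided_at: datetime

    def __post_init__(self):
        if len(set(self.identifiers)) != self.n_drift:
            raise ValueError("identifiers must hold n_drift distinct entries")


class PlannerAgent:
    """Polls the knowledge base and decides per tumbling decision window.

    The decision rule is injected (``decide(window_start_ms, window_end_ms,
    records) -> Alert | None``) so different voting policies can share the
    polling/watermark machinery.  Windows are keyed on ``datetime_monitored``
    relative to ``origin`` so decisions are independent of processing
    latency; a window is decided once a record beyond its end has been seen
    (watermark), or at :meth:`finalize`.
    """

    def __init__(
        self,
        kb: KnowledgeBase,
        decide: Callable[[int, int, Sequence[PredictionRecord]], Optional[Alert]],
        origin: datetime,
        window_ms: int = 1000,
        registry: Optional[Registry] = None,
        jid: str = "planner",
    ) -> None:
        if window_ms <= 0:
            raise ValueError(f"window_ms must be > 0, got {window_ms}")
        self.kb = kb
        self.decide = decide
        self.origin = origin
        self.window_ms = int(window_ms)
        self.jid = jid
        self._cursor = 0
        self._pending: Dict[int, List[PredictionRecord]] = {}
        self._decided: set[int] = set()
        self._watermark: Optional[int] = None
        self.alerts: List[Alert] = []
        if registry is not None and jid not in registry.agents:
            registry.register(AgentDescriptor(jid=jid, role="planner"))

    def _window_of(self, record: PredictionRecord) -> int:
        ms = (record.datetime_monitored - self.origin) / timedelta(milliseconds=1)
        return int(ms // self.window_ms)

    def poll(self) -> List[PredictionRecord]:
        """Fetch records not seen by previous polls (never twice)."""
        try:
            records, self._cursor = self.kb.poll_new(self._cursor)
        except Exception as exc:  # KB unavailable: degrade, do not crash
            logging.getLogger("driftmon").warning(
                json.dumps({"event": "poll_failed", "error": str(exc)})
            )
            return []
        _log("poll", planner=self.jid, new_records=len(records))
        return records

    def _decide_window(self, w: int) -> Optional[Alert]:
        records = self._pending.pop(w, [])
        self._decided.add(w)
        alert = self.decide(w * self.window_ms, (w + 1) * self.window_ms, records)
        if alert is not None:
            self.alerts.append(alert)
            _log("alert", planner=self.jid, window_start_ms=alert.window_start_ms,
                 n_drift=alert.n_drift, identifiers=list(alert.identifiers))
        return alert

    def step(self) -> List[Alert]:
        """Poll once and decide every window the watermark has passed."""
        fired: List[Alert] = []
        for record in self.poll():
            w = self._window_of(record)
            if w in self._decided:
                continue  # late record for an already-decided window
            self._pending.setdefault(w, []).append(record)
            self._watermark = w if self._watermark is None else max(self._watermark, w)
        if self._watermark is not None:
            for w in sorted(list(self._pending)):
                if w < self._watermark:
                    alert = self._decide_window(w)
                    if alert is not None:
                        fired.append(alert)
        return fired

    def finalize(self) -> List[Alert]:
        """Decide all still-pending windows (end of stream)."""
        fired = []
        for w in sorted(list(self._pending)):
            alert = self._decide_window(w)
            if alert is not None:
                fired.append(alert)
        return fired


class Sink(Protocol):  # pragma: no cover - typing aid
    alive: bool

    def append(self, alert: Alert) -> None: ...


@dataclass
class ListSink:
    """In-memory sink; flip ``alive`` to exercise back-pressure."""

    alive: bool = True
    items: List[Alert] = field(default_factory=list)

    def append(self, alert: Alert) -> None:
        if not self.alive:
            raise IOError("sink unavailable")
        self.items.append(alert)


class ExecutorAgent:
    """Delivers alerts to a sink, holding them while the sink is down.

    The executor knows whether the sink is available and informs the planner
    (``accepting``) so it stops forwarding; held alerts are delivered in
    their original order once the sink recovers.
    """

    def __init__(self, sink, registry: Optional[Registry] = None,
                 jid: str = "executor") -> None:
        self.sink = sink
        self.jid = jid
        self.held: List[Alert] = []
        self.delivered: int = 0
        if registry is not None and jid not in registry.agents:
            registry.register(AgentDescriptor(jid=jid, role="executor"))

    @property
    def accepting(self) -> bool:
        """What the executor tells the planner about forwarding."""
        return bool(getattr(self.sink, "alive", True))

    def _try_append(self, alert: Alert) -> bool:
        if not self.accepting:
            return False
        try:
            self.sink.append(alert)
        except Exception:
            return False
        return True

    def pump(self) -> int:
        """Drain held alerts in order while the sink accepts them."""
        n = 0
        while self.held and self._try_append(self.held[0]):
            self.held.pop(0)
            self.delivered += 1
            n += 1
        return n

    def deliver(self, alert: Alert) -> str:
        """Deliver (or hold) one alert; returns "delivered" or "held"."""
        self.pump()
        if self.held or not self._try_append(alert):
            self.held.append(alert)
            _log("hold", executor=self.jid, held=len(self.held))
            return "held"
        self.delivered += 1
        _log("deliver", executor=self.jid,
             window_start_ms=alert.window_start_ms, n_drift=alert.n_drift)
        return "delivered"
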