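"""End-to-end health-monitor pipeline for 8-channel EMG recordings.

A recording (headerless delimited text, one row per millisecond, one column
per muscle) is fanned out row by row: each channel's monitor forwards its
sample to the channel's analyser, which runs the adaptive-window drift
detector (with the adaptive-delta training loop) and persists every
prediction to the knowledge base.  The planner partitions stream time into
consecutive (tumbling) 1-second decision windows keyed on the *monitored*
timestamp and applies a voting rule per window:

    alert  iff  min_drifts <= n_drift < max_drifts        (default 2 <= n < 8)

where ``n_drift`` is the number of *distinct* muscles with at least one
drift-flagged prediction in the window.  Requiring at least two muscles
filters single-channel false positives (the limbs carry muscle pairs, so a
real physiological change shows on at least two channels); excluding the
all-channels case guards against the cold start, when every detector is
still calibrating and flags together.  Fired alerts are appended by the
executor to a CSV sink.

All timestamps are logical stream time anchored at a fixed epoch, so a rerun
of the same input and config is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from .adwin import AdwinDetector
from .agents import (
    Alert,
    AnalyserAgent,
    ExecutorAgent,
    LogicalClock,
    MonitorAgent,
    PlannerAgent,
    Registry,
    Sample,
)
from .config import PipelineConfig
from .delta import DeltaController
from .kb import KnowledgeBase, PredictionRecord, SQLiteKnowledgeBase
from .synthetic import read_csv

__all__ = [
    "PlannerRule",
    "vote",
    "plan_kb",
    "CsvAlertSink",
    "RunSummary",
    "run_pipeline",
    "STREAM_EPOCH",
    "ALERT_HEADER",
]

logger = logging.getLogger("driftmon")

# fixed anchor for logical stream time: keeps reruns byte-identical
STREAM_EPOCH = datetime(2000, 1, 1, 0, 0, 0)

ALERT_HEADER = "window_start_ms,window_end_ms,n_drift,identifiers,decided_at"


@dataclass(frozen=True)
class PlannerRule:
    """Voting thresholds: alert iff min_drifts <= n_drift < max_drifts."""

    min_drifts: int = 2
    max_drifts: int = 8
    decision_window_ms: int = 1000

    def __post_init__(self):
        if not (1 <= self.min_drifts < self.max_drifts):
            raise ValueError(
                f"need 1 <= min_drifts < max_drifts, got "
                f"{self.min_drifts}, {self.max_drifts}"
            )
        if self.decision_window_ms <= 0:
            raise ValueError(
                f"decision_window_ms must be > 0, got {self.decision_window_ms}"
            )


def vote(
    records: Sequence[PredictionRecord],
    rule: PlannerRule,
    window_start_ms: int = 0,
    window_end_ms: Optional[int] = None,
    decided_at: Optional[datetime] = None,
) -> Optional[Alert]:
    """Decide one window: count distinct drifting channels and apply the rule.

    ``n_drift`` counts muscles, not prediction records — five flagged
    records on one channel still count as one drifting muscle.
    """
    if window_end_ms is None:
        window_end_ms = window_start_ms + rule.decision_window_ms
    drifting = sorted({r.identifier for r in records if r.predicted})
    n_drift = len(drifting)
    if not rule.min_drifts <= n_drift < rule.max_drifts:
        return None
    if decided_at is None:
        decided_at = STREAM_EPOCH + timedelta(milliseconds=window_end_ms)
    return Alert(
        window_start_ms=window_start_ms,
        window_end_ms=window_end_ms,
        n_drift=n_drift,
        identifiers=tuple(drifting),
        decided_at=decided_at,
    )


def plan_kb(
    kb: KnowledgeBase,
    rule: PlannerRule,
    executor: Optional[ExecutorAgent] = None,
    origin: datetime = STREAM_EPOCH,
) -> List[Alert]:
    """Replay a knowledge base through the planner in one batch.

    Partitions all stored predictions into tumbling decision windows by
    ``datetime_monitored`` and votes per window; alerts go to the executor
    (which holds them if the sink is down) when one is given.  Planner
    decisions are a function of knowledge-base contents only, so replaying
    the same KB yields identical alerts.
    """
    planner = PlannerAgent(
        kb,
        lambda s, e, recs: vote(recs, rule, s, e),
        origin=origin,
        window_ms=rule.decision_window_ms,
    )
    planner.step()
    planner.finalize()
    alerts = planner.alerts
    if executor is not None:
        for alert in alerts:
            executor.deliver(alert)
    return alerts


class CsvAlertSink:
    """Append-only CSV sink for fired alerts."""

    def __init__(self, path: Union[str, Path]):
        self.path = Path(path)
        self.alive = True
        self.path.write_text(ALERT_HEADER + "\n", encoding="utf-8")

    def append(self, alert: Alert) -> None:
        if not self.alive:
            raise IOError(f"sink unavailable: {self.path}")
        row = (
            f"{alert.window_start_ms},{alert.window_end_ms},{alert.n_drift},"
            f"{';'.join(alert.identifiers)},"
            f"{alert.decided_at.isoformat(sep=' ', timespec='milliseconds')}\n"
        )
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(row)


@dataclass
class RunSummary:
    """What one pipeline run did, channel by channel."""

    rows_read: int = 0
    rows_skipped: int = 0
    skipped_lines: List[tuple] = field(default_factory=list)
    predictions_written: int = 0
    raw_drifts: Dict[str, int] = field(default_factory=dict)
    alerts_fired: int = 0
    alerts: List[Alert] = field(default_factory=list)
    training_ops_in_predict: int = 0
    retrain_calls: int = 0

    @property
    def raw_drift_total(self) -> int:
        return sum(self.raw_drifts.values())

    def as_dict(self) -> dict:
        return {
            "rows_read": self.rows_read,
            "rows_skipped": self.rows_skipped,
            "predictions_written": self.predictions_written,
            "raw_drifts": dict(self.raw_drifts),
            "raw_drift_total": self.raw_drift_total,
            "alerts_fired": self.alerts_fired,
            "training_ops_in_predict": self.training_ops_in_predict,
            "retrain_calls": self.retrain_calls,
        }

    def render(self) -> str:
        lines = [
            f"rows read:            {self.rows_read}",
            f"rows skipped:         {self.rows_skipped}",
            f"predictions written:  {self.predictions_written}",
            f"raw drifts total:     {self.raw_drift_total}",
        ]
        for name in sorted(self.raw_drifts):
            lines.append(f"  {name:<18} {self.raw_drifts[name]}")
        lines.append(f"alerts fired:         {self.alerts_fired}")
        return "\n".join(lines)


def run_pipeline(
    input_path: Union[str, Path],
    config: Optional[PipelineConfig] = None,
    kb: Optional[KnowledgeBase] = None,
    out_path: Union[str, Path, None] = None,
) -> RunSummary:
    """Run a whole recording through monitors, analysers, planner, executor.

    Every input row fans out as one sample per channel; malformed rows are
    skipped with a line-numbered diagnostic and counted in the summary.
    Returns the run summary; the populated knowledge base and the alerts
    CSV (when ``out_path`` is given) are the side effects.
    """
    config = config or PipelineConfig()
    channels = config.channels
    matrix, issues = read_csv(input_path, n_channels=len(channels), on_bad="skip")
    if kb is None:
        kb = SQLiteKnowledgeBase(":memory:")
    clock = LogicalClock(STREAM_EPOCH)
    registry = Registry()
    rule = PlannerRule(
        min_drifts=config.planner.min_drifts,
        max_drifts=config.planner.max_drifts,
        decision_window_ms=config.planner.window_ms,
    )

    monitors: List[MonitorAgent] = []
    analysers: List[AnalyserAgent] = []
    for name in channels:
        monitor = MonitorAgent(f"monitor_{name}", registry)
        analyser = AnalyserAgent(
            jid=f"analyser_{name}",
            identifier=name,
            detector=AdwinDetector(delta=config.delta.start),
            controller=DeltaController(
                start=config.delta.start,
                lower=config.delta.lower,
                upper=config.delta.upper,
                chunk_size=config.delta.chunk_size,
            ),
            kb=kb,
            clock=clock,
            registry=registry,
            calibration_n=config.calibration_ms,  # 1 sample per ms
        )
        registry.subscribe(analyser.jid, monitor.jid)
        monitors.append(monitor)
        analysers.append(analyser)
    by_jid = {a.jid: a for a in analysers}

    sink = CsvAlertSink(out_path) if out_path is not None else None
    executor = ExecutorAgent(sink if sink is not None else _NullSink(), registry)
    planner = PlannerAgent(
        kb,
        lambda s, e, recs: vote(recs, rule, s, e),
        origin=STREAM_EPOCH,
        window_ms=rule.decision_window_ms,
        registry=registry,
    )

    summary = RunSummary(rows_skipped=len(issues), skipped_lines=list(issues))
    for lineno, msg in issues:
        logger.warning('{"event": "bad_row", "line": %d, "reason": "%s"}', lineno, msg)

    for t, row in enumerate(matrix):
        when = STREAM_EPOCH + timedelta(milliseconds=t)
        clock.advance_to(when)
        for monitor, name, value in zip(monitors, channels, row):
            sample = Sample(
                identifier=name,
                value=float(value),
                timestamp_ms=t,
                monitored_at=when,
            )
            for analyser_jid in monitor.emit(sample):
                by_jid[analyser_jid].handle(sample)
        # retraining runs as a separate task, never inside the predict path
        for analyser in analysers:
            analyser.retrain_if_due()
        for alert in planner.step():
            executor.deliver(alert)
        summary.rows_read += 1
    for alert in planner.finalize():
        executor.deliver(alert)
    executor.pump()
    if hasattr(kb, "commit"):
        kb.commit()

    summary.predictions_written = kb.count()
    summary.raw_drifts = {
        name: kb.count(predicted_only=True, identifier=name) for name in channels
    }
    summary.alerts = list(planner.alerts)
    summary.alerts_fired = len(planner.alerts)
    summary.training_ops_in_predict = sum(
        a.counters["training_ops_in_predict"] for a in analysers
    )
    summary.retrain_calls = sum(a.counters["retrain_calls"] for a in analysers)
    return summary


class _NullSink:
    alive = True

    def append(self, alert: Alert) -> None:
        pass
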