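"""Shared knowledge base: the append-only log of every analyser prediction.

Each row records who analysed what and when, and whether a concept drift was
flagged:

    jid                 name of the analyser that made the prediction
    data                monitored payload as canonical JSON, e.g. {"sensor":429}
    datetime_monitored  when the monitor collected the sample
    datetime_analysed   when the analyser predicted on it
    identifier          channel (muscle) name, e.g. "left_thigh"
    predicted           boolean drift verdict

The schema is relational and backend-neutral; the default backend is an
embedded single-file SQLite store (plus an auto-increment surrogate key —
the schema itself defines no primary key).  An in-memory list backend with
the identical interface exists for tests and for wiring other relational
engines behind the same surface.

Two query patterns are served: the planner polls for new predictions (cursor
based, no record is ever returned twice) and analysers fetch recent
per-channel history for retraining.  Timestamps are stored with millisecond
precision (ISO-8601, space separated): 1 kHz data needs finer grain than
whole seconds for 1-second planner windows.  The JSON payload is serialised
canonically (sorted keys, no extra whitespace) so round trips are
byte-stable.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, List, Optional, Tuple, Union

__all__ = [
    "PredictionRecord",
    "KnowledgeBase",
    "SQLiteKnowledgeBase",
    "InMemoryKnowledgeBase",
    "canonical_json",
]


def canonical_json(data: dict) -> str:
    """Canonical serialisation of the payload column (sorted keys, compact)."""
    return json.dumps(data, sort_keys=True, separators=(",", ":"))


def _fmt(ts: datetime) -> str:
    return ts.isoformat(sep=" ", timespec="milliseconds")


def _parse(ts: str) -> datetime:
    return datetime.fromisoformat(ts)


@dataclass(frozen=True)
class PredictionRecord:
    """One prediction row (see module docstring for column meanings)."""

    jid: str
    data: dict
    datetime_monitored: datetime
    datetime_analysed: datetime
    identifier: str
    predicted: bool

    def validate(self) -> None:
        if not self.jid:
            raise ValueError("jid must be non-empty")
        if not self.identifier:
            raise ValueError("identifier must be non-empty")
        if not isinstance(self.predicted, bool):
            raise ValueError(f"predicted must be a bool, got {self.predicted!r}")
        if self.datetime_analysed < self.datetime_monitored:
            raise ValueError(
                "datetime_analysed must be >= datetime_monitored "
                f"({self.datetime_analysed} < {self.datetime_monitored})"
            )
        if not isinstance(self.data, dict):
            raise ValueError(f"data must be a JSON object, got {type(self.data)}")
        canonical_json(self.data)  # raises if not serialisable

    def normalised(self) -> "PredictionRecord":
        """Copy with timestamps truncated to stored (millisecond) precision."""
        return PredictionRecord(
            jid=self.jid,
            data=json.loads(canonical_json(self.data)),
            datetime_monitored=_parse(_fmt(self.datetime_monitored)),
            datetime_analysed=_parse(_fmt(self.datetime_analysed)),
            identifier=self.identifier,
            predicted=self.predicted,
        )


class KnowledgeBase:
    """Interface shared by every backend.

    Inserts are append-only; there are no updates or deletes.
    """

    def insert_prediction(self, record: PredictionRecord) -> None:
        raise NotImplementedError

    def query_window(
        self,
        since: datetime,
        until: datetime,
        predicted_only: bool = False,
    ) -> List[PredictionRecord]:
        """Records with since < datetime_analysed <= until, ordered by
        (datetime_analysed, jid)."""
        raise NotImplementedError

    def query_training(self, identifier: str, limit: int) -> List[PredictionRecord]:
        """Most recent `limit` records for one channel, oldest first."""
        raise NotImplementedError

    def poll_new(self, cursor: int) -> Tuple[List[PredictionRecord], int]:
        """Records appended after `cursor`, in insertion order, plus the new
        cursor.  Repeated polls never return a record twice."""
        raise NotImplementedError

    def count(self, predicted_only: bool = False, identifier: Optional[str] = None) -> int:
        raise NotImplementedError


_SCHEMA = """
CREATE TABLE IF NOT EXISTS predictions (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    jid TEXT NOT NULL,
    data TEXT NOT NULL,
    datetime_monitored TEXT NOT NULL,
    datetime_analysed TEXT NOT NULL,
    identifier TEXT NOT NULL,
    predicted INTEGER NOT NULL CHECK (predicted IN (0, 1))
);
CREATE INDEX IF NOT EXISTS idx_pred_analysed ON predictions (datetime_analysed);
CREATE INDEX IF NOT EXISTS idx_pred_identifier ON predictions (identifier, id);
"""


class SQLiteKnowledgeBase(KnowledgeBase):
    """Embedded single-file relational backend (":memory:" for ephemeral)."""

    def __init__(self, path: Union[str, Path] = ":memory:") -> None:
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.commit()
        self._conn.close()

    def insert_prediction(self, record: PredictionRecord) -> None:
        record.validate()
        self._conn.execute(
            "INSERT INTO predictions "
            "(jid, data, datetime_monitored, datetime_analysed, identifier, predicted) "
            "VALUES (?, ?, ?, ?, ?, ?)",
            (
                record.jid,
                canonical_json(record.data),
                _fmt(record.datetime_monitored),
                _fmt(record.datetime_analysed),
                record.identifier,
                int(record.predicted),
            ),
        )

    def insert_many(self, records: Iterable[PredictionRecord]) -> None:
        for r in records:
            self.insert_prediction(r)
        self._conn.commit()

    @staticmethod
    def _row_to_record(row) -> PredictionRecord:
        jid, data, mon, ana, ident, pred = row
        return PredictionRecord(
            jid=jid,
            data=json.loads(data),
            datetime_monitored=_parse(mon),
            datetime_analysed=_parse(ana),
            identifier=ident,
            predicted=bool(pred),
        )

    _COLS = "jid, data, datetime_monitored, datetime_analysed, identifier, predicted"

    def query_window(self, since, until, predicted_only=False):
        if since > until:
            raise ValueError(f"since must be <= until ({since} > {until})")
        sql = (
            f"SELECT {self._COLS} FROM predictions "
            "WHERE datetime_analysed > ? AND datetime_analysed <= ?"
        )
        args = [_fmt(since), _fmt(until)]
        if predicted_only:
            sql += " AND predicted = 1"
        sql += " ORDER BY datetime_analysed, jid, id"
        return [self._row_to_record(r) for r in self._conn.execute(sql, args)]

    def query_training(self, identifier, limit):
        if limit < 0:
            raise ValueError(f"limit must be >= 0, got {limit}")
        rows = list(
            self._conn.execute(
                f"SELECT {self._COLS} FROM predictions WHERE identifier = ? "
                "ORDER BY id DESC LIMIT ?",
                (identifier, limit),
            )
        )
        return [self._row_to_record(r) for r in reversed(rows)]

    def poll_new(self, cursor):
        rows = list(
            self._conn.execute(
                f"SELECT id, {self._COLS} FROM predictions WHERE id > ? ORDER BY id",
                (cursor,),
            )
        )
        if not rows:
            return [], cursor
        return [self._row_to_record(r[1:]) for r in rows], rows[-1][0]

    def count(self, predicted_only=False, identifier=None):
        sql = "SELECT COUNT(*) FROM predictions WHERE 1=1"
        args: list = []
        if predicted_only:
            sql += " AND predicted = 1"
        if identifier is not None:
            sql += " AND identifier = ?"
            args.append(identifier)
        return self._conn.execute(sql, args).fetchone()[0]

    def commit(self) -> None:
        self._conn.commit()


class InMemoryKnowledgeBase(KnowledgeBase):
    """List-backed backend with the identical contract (tests, prototyping)."""

    def __init__(self) -> None:
        self._rows: list[Tuple[int, PredictionRecord]] = []
        self._next_id = 1

    def insert_prediction(self, record):
        record.validate()
        self._rows.append((self._next_id, record.normalised()))
        self._next_id += 1

    def query_window(self, since, until, predicted_only=False):
        if since > until:
            raise ValueError(f"since must be <= until ({since} > {until})")
        hits = [
            (rid, r)
            for rid, r in self._rows
            if since < r.datetime_analysed <= until
            and (r.predicted or not predicted_only)
        ]
        hits.sort(key=lambda t: (t[1].datetime_analysed, t[1].jid, t[0]))
        return [r for _, r in hits]

    def query_training(self, identifier, limit):
        if limit < 0:
            raise ValueError(f"limit must be >= 0, got {limit}")
        mine = [r for _, r in self._rows if r.identifier == identifier]
        return mine[-limit:] if limit else []

    def poll_new(self, cursor):
        new = [(rid, r) for rid, r in self._rows if rid > cursor]
        if not new:
            return [], cursor
        return [r for _, r in new], new[-1][0]

    def count(self, predicted_only=False, identifier=None):
        return sum(
            1
            for _, r in self._rows
            if (r.predicted or not predicted_only)
            and (identifier is None or r.identifier == identifier)
        )

    def commit(self) -> None:  # interface parity with the SQLite backend
        pass

    def close(self) -> None:
        pass
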