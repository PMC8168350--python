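from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from driftmon.kb import InMemoryKnowledgeBase, PredictionRecord, SQLiteKnowledgeBase


EPOCH = datetime(2000, 1, 1)


def make_record(
    jid="analyser_left_thigh",
    sensor=429,
    monitored_ms=0,
    analysed_ms=None,
    identifier="left_thigh",
    predicted=False,
):
    analysed_ms = monitored_ms if analysed_ms is None else analysed_ms
    return PredictionRecord(
        jid=jid,
        data={"sensor": sensor},
        datetime_monitored=EPOCH + timedelta(milliseconds=monitored_ms),
        datetime_analysed=EPOCH + timedelta(milliseconds=analysed_ms),
        identifier=identifier,
        predicted=predicted,
    )


@pytest.fixture(params=["sqlite_memory", "sqlite_file", "in_memory"])
def kb(request, tmp_path):
    """The same contract must hold on every knowledge-base backend."""
    if request.param == "sqlite_memory":
        store = SQLiteKnowledgeBase(":memory:")
    elif request.param == "sqlite_file":
        store = SQLiteKnowledgeBase(tmp_path / "kb.sqlite")
    else:
        store = InMemoryKnowledgeBase()
    yield store
    store.close()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
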