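"""Configuration schema and YAML loading for the monitoring pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import yaml

from .synthetic import DEFAULT_CHANNELS, DriftEvent, SyntheticConfig

__all__ = [
    "DeltaConfig",
    "PlannerConfig",
    "PipelineConfig",
    "load_config",
    "ConfigError",
]


class ConfigError(ValueError):
    pass


@dataclass
class DeltaConfig:
    """Detector-confidence regulation settings (per channel)."""

    start: float = 1.0
    lower: float = 1e-9
    upper: float = 1.0
    chunk_size: int = 2000  # samples per training step (2 s at 1 sample/ms)


@dataclass
class PlannerConfig:
    """Voting rule: alert iff min_drifts <= n_drift < max_drifts per window."""

    min_drifts: int = 2
    max_drifts: int = 8
    window_ms: int = 1000

    def __post_init__(self):
        if not (1 <= self.min_drifts < self.max_drifts):
            raise ConfigError(
                f"need 1 <= min_drifts < max_drifts, got "
                f"{self.min_drifts}, {self.max_drifts}"
            )
        if self.window_ms <= 0:
            raise ConfigError(f"window_ms must be > 0, got {self.window_ms}")


@dataclass
class PipelineConfig:
    channels: List[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    delta: DeltaConfig = field(default_factory=DeltaConfig)
    planner: PlannerConfig = field(default_factory=PlannerConfig)
    calibration_ms: int = 1000
    sink: str = "alerts.csv"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self):
        if len(set(self.channels)) != len(self.channels):
            raise ConfigError("channel names must be distinct")
        if not self.channels:
            raise ConfigError("at least one channel is required")
        if self.calibration_ms < 0:
            raise ConfigError("calibration_ms must be >= 0")


def _build_events(raw: list) -> List[DriftEvent]:
    events = []
    for item in raw:
        events.append(
            DriftEvent(
                at_ms=int(item["at_ms"]),
                channels=tuple(int(c) for c in item["channels"]),
                kind=item["kind"],
                magnitude=float(item["magnitude"]),
                duration_ms=int(item.get("duration_ms", 0)),
            )
        )
    return events


def load_config(path: Union[str, Path, None]) -> PipelineConfig:
    """Load a YAML pipeline config; None or a missing block means defaults."""
    if path is None:
        return PipelineConfig()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        delta = DeltaConfig(**raw.get("delta", {}))
        planner = PlannerConfig(**raw.get("planner", {}))
        syn_raw = dict(raw.get("synthetic", {}))
        syn_raw["events"] = _build_events(syn_raw.get("events", []))
        synthetic = SyntheticConfig(**syn_raw)
        return PipelineConfig(
            channels=list(raw.get("channels", DEFAULT_CHANNELS)),
            delta=delta,
            planner=planner,
            calibration_ms=int(raw.get("calibration_ms", 1000)),
            sink=str(raw.get("sink", "alerts.csv")),
            synthetic=synthetic,
        )
    except (TypeError, KeyError, ValueError) as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
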