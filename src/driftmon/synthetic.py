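"""Synthetic multi-channel EMG-like streams with injectable drift events.

Emulates the shape of surface-EMG action-potential recordings as used by the
monitoring pipeline: 8 muscle channels, one row per millisecond, zero-centred
spiky noise in microvolts.  The default noise family is Laplace — heavy
enough in the tails to produce the spike-rich look of real EMG while keeping
all moments finite — and values are rounded to integer microvolt counts to
match the ``{"sensor": 429}`` payload style of the knowledge base.

Drift events are deterministic transforms of the base noise draw:

* ``variance_scale`` multiplies the variance by ``magnitude`` (so the
  standard deviation by ``sqrt(magnitude)``) over the event span;
* ``mean_shift`` adds ``magnitude`` channel standard deviations.

Because events transform an already-drawn base matrix, channels not named in
any event are bit-identical to an event-free run with the same seed, and a
run is fully reproducible from its seed.  Overlapping events of the same
kind on one channel contradict each other; the later-listed event wins, with
a warning.

This module also reads and writes the headerless 8-column delimited text
dialect of public physical-action EMG recordings (comma, tab, or whitespace
separated; one row per time step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Literal, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "DriftEvent",
    "SyntheticConfig",
    "generate",
    "write_csv",
    "read_csv",
    "CsvParseError",
    "DEFAULT_CHANNELS",
]

# the dataset's 8 muscles: right/left x bicep/tricep/thigh/hamstring
DEFAULT_CHANNELS = (
    "right_bicep",
    "right_tricep",
    "left_bicep",
    "left_tricep",
    "right_thigh",
    "right_hamstring",
    "left_thigh",
    "left_hamstring",
)

EventKind = Literal["variance_scale", "mean_shift"]


@dataclass(frozen=True)
class DriftEvent:
    """One injected distribution change.

    ``magnitude`` is a variance multiplier for ``variance_scale`` and an
    offset in channel-sigma units for ``mean_shift``.  ``duration_ms = 0``
    means the event persists to the end of the stream.
    """

    at_ms: int
    channels: Tuple[int, ...]
    kind: EventKind
    magnitude: float
    duration_ms: int = 0

    def __post_init__(self):
        if self.at_ms < 0:
            raise ValueError(f"at_ms must be >= 0, got {self.at_ms}")
        if not self.channels:
            raise ValueError("channels must be non-empty")
        if self.kind not in ("variance_scale", "mean_shift"):
            raise ValueError(f"unknown event kind: {self.kind!r}")
        if self.kind == "variance_scale" and self.magnitude <= 0:
            raise ValueError("variance_scale magnitude must be > 0")
        if self.duration_ms < 0:
            raise ValueError(f"duration_ms must be >= 0, got {self.duration_ms}")

    def span(self, n_samples: int) -> Tuple[int, int]:
        end = n_samples if self.duration_ms == 0 else min(
            n_samples, self.at_ms + self.duration_ms
        )
        return min(self.at_ms, n_samples), end


@dataclass
class SyntheticConfig:
    """Generation recipe: 1 sample/ms per channel, zero-centred noise.

    ``base_sigma`` is the per-channel standard deviation in microvolts
    (scalar, broadcast to all channels, or one value per channel).
    """

    n_samples: int = 10_000
    n_channels: int = 8
    base_sigma: Union[float, Sequence[float]] = 100.0
    noise: Literal["laplace", "normal"] = "laplace"
    events: List[DriftEvent] = field(default_factory=list)
    seed: int = 0
    integer_uV: bool = True

    def sigmas(self) -> np.ndarray:
        s = np.broadcast_to(
            np.asarray(self.base_sigma, dtype=float), (self.n_channels,)
        ).copy()
        if np.any(s < 0):
            raise ValueError("base_sigma must be >= 0")
        return s

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.noise not in ("laplace", "normal"):
            raise ValueError(f"unknown noise family: {self.noise!r}")
        self.sigmas()
        for ev in self.events:
            for c in ev.channels:
                if not 0 <= c < self.n_channels:
                    raise ValueError(f"event channel {c} out of range")


def generate(config: SyntheticConfig) -> np.ndarray:
    """Draw an (n_samples, n_channels) matrix in microvolts.

    Fully reproducible from ``config.seed``; events only touch the channels
    they name (see module docstring for the overlap rule).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sig = config.sigmas()
    n, c = config.n_samples, config.n_channels
    if config.noise == "laplace":
        base = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=(n, c))  # unit variance
    else:
        base = rng.normal(0.0, 1.0, size=(n, c))
    scale = np.ones((n, c))
    offset = np.zeros((n, c))
    for ev in config.events:
        lo, hi = ev.span(n)
        for ch in ev.channels:
            if ev.kind == "variance_scale":
                if np.any(scale[lo:hi, ch] != 1.0):
                    warnings.warn(
                        f"overlapping variance_scale events on channel {ch}; "
                        "later-listed event wins",
                        stacklevel=2,
                    )
                scale[lo:hi, ch] = np.sqrt(ev.magnitude)
            else:
                if np.any(offset[lo:hi, ch] != 0.0):
                    warnings.warn(
                        f"overlapping mean_shift events on channel {ch}; "
                        "later-listed event wins",
                        stacklevel=2,
                    )
                offset[lo:hi, ch] = ev.magnitude * sig[ch]
    out = base * scale * sig[np.newaxis, :] + offset
    if config.integer_uV:
        out = np.rint(out)
    return out


class CsvParseError(ValueError):
    """Raised for unreadable rows; carries 1-based line numbers."""

    def __init__(self, issues: List[Tuple[int, str]]):
        self.issues = issues
        lines = "; ".join(f"line {n}: {msg}" for n, msg in issues[:10])
        extra = "" if len(issues) <= 10 else f" (+{len(issues) - 10} more)"
        super().__init__(f"unparseable rows: {lines}{extra}")


def write_csv(matrix: np.ndarray, path: Union[str, Path], delimiter: str = ",") -> None:
    """Write the headerless delimited dialect (one row per time step)."""
    arr = np.asarray(matrix)
    if arr.ndim != 2:
        raise ValueError(f"matrix must be 2-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("matrix must be finite")
    if np.allclose(arr, np.rint(arr)):
        fmt = "%d"
        arr = np.rint(arr).astype(np.int64)
    else:
        fmt = "%.6g"
    np.savetxt(path, arr, fmt=fmt, delimiter=delimiter)


def _sniff_delimiter(line: str) -> Optional[str]:
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # any whitespace


def read_csv(
    path: Union[str, Path],
    n_channels: int = 8,
    on_bad: Literal["raise", "skip"] = "raise",
) -> Tuple[np.ndarray, List[Tuple[int, str]]]:
    """Read the headerless dialect, auto-detecting the delimiter.

    Returns ``(matrix, issues)`` where issues is a list of
    ``(1-based line number, message)`` for rows with the wrong column count
    or non-numeric cells.  With ``on_bad="raise"`` any issue raises
    :class:`CsvParseError`; with ``"skip"`` bad rows are dropped and
    reported.
    """
    rows: List[List[float]] = []
    issues: List[Tuple[int, str]] = []
    delim: Optional[str] = None
    sniffed = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if not sniffed:
                delim = _sniff_delimiter(line)
                sniffed = True
            parts = line.split(delim) if delim else line.split()
            parts = [p for p in parts if p != ""]
            if len(parts) != n_channels:
                issues.append(
                    (lineno, f"expected {n_channels} columns, found {len(parts)}")
                )
                continue
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                bad = next(p for p in parts if not _is_number(p))
                issues.append((lineno, f"non-numeric cell {bad!r}"))
    if issues and on_bad == "raise":
        raise CsvParseError(issues)
    matrix = (
        np.asarray(rows, dtype=float)
        if rows
        else np.empty((0, n_channels), dtype=float)
    )
    return matrix, issues


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
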