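"""Adaptive regulation of the detector confidence delta from the drift rate.

Each monitored stream gets its own controller.  The feedback signal is the
*drift rate* — the accumulated number of drift detections divided by the
number of samples analysed over the stream's lifetime.  At the end of every
training chunk (2,000 samples by default, i.e. 2 s at 1 sample/ms) the
controller compares the current rate with the rate recorded at the last
delta change (``last_rate``):

* rate increasing  -> delta is divided by 10 (less sensitive), if the lower
  boundary permits;
* rate decreasing  -> delta is multiplied by 10 (more sensitive), if the
  upper boundary permits;
* equal rates, or a move blocked by a boundary -> nothing changes, and in
  particular ``last_rate`` is *not* updated (this is the noise guard: a
  blocked move must not silently re-anchor the comparison).

delta always starts at the upper boundary (1.0 by default, ultra-sensitive)
and only ever takes values ``upper * 10**(-k)`` for integer k >= 0, so the
exponent is stored as an integer and the float value is recomputed — the
decade invariant holds exactly, with no accumulation of rounding error.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence, Tuple, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .adwin import AdwinDetector

__all__ = ["DeltaController"]


class DeltaController:
    """Decade-stepping delta controller (one per monitored stream).

    Parameters
    ----------
    start:
        Initial delta; must be ``upper * 10**(-k)`` for some integer k >= 0.
    lower, upper:
        Saturation boundaries for delta.
    chunk_size:
        Samples per training step (default 2,000 = 2 s at 1 sample/ms).
    """

    def __init__(
        self,
        start: float = 1.0,
        lower: float = 1e-9,
        upper: float = 1.0,
        chunk_size: int = 2000,
    ) -> None:
        if not (0.0 < lower <= upper <= 1.0):
            raise ValueError(
                f"need 0 < lower <= upper <= 1, got lower={lower}, upper={upper}"
            )
        if chunk_size < 1:
            raise ValueError(f"chunk_size must be >= 1, got {chunk_size}")
        self.lower = float(lower)
        self.upper = float(upper)
        self.chunk_size = int(chunk_size)
        k = round(math.log10(upper / start))
        if k < 0 or not math.isclose(upper * 10.0 ** (-k), start, rel_tol=1e-9):
            raise ValueError(
                f"start must be upper*10**-k for integer k>=0, got {start}"
            )
        self._decade = k
        self.last_rate = 0.0
        self.drifts_accumulated = 0
        self.samples_analysed = 0

    # -- state ------------------------------------------------------------

    @property
    def delta(self) -> float:
        return self.upper * 10.0 ** (-self._decade)

    @property
    def decade(self) -> int:
        """Non-negative integer k with delta == upper * 10**-k."""
        return self._decade

    def drift_rate(self) -> float:
        """Accumulated drift detections over samples analysed (0 if none yet)."""
        if self.samples_analysed == 0:
            return 0.0
        return self.drifts_accumulated / self.samples_analysed

    # -- the adaptation rule ----------------------------------------------

    def step_delta(self, rate: float) -> None:
        """Apply one decade move given the current drift rate.

        At most one decade per call; saturates silently at the boundaries
        (``last_rate`` untouched when the move is blocked or the rate is
        unchanged).
        """
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate must be in [0, 1], got {rate}")
        if rate > self.last_rate:
            candidate = self.upper * 10.0 ** (-(self._decade + 1))
            if candidate >= self.lower:
                self._decade += 1
                self.last_rate = rate
        elif rate < self.last_rate:
            if self._decade >= 1:  # delta*10 <= upper iff a decade was used
                self._decade -= 1
                self.last_rate = rate

    # -- bookkeeping used by the agent runtime ----------------------------

    def absorb(self, n_samples: int, n_drifts: int) -> None:
        """Account for analysed samples and detected drifts."""
        if n_drifts > n_samples or n_samples < 0 or n_drifts < 0:
            raise ValueError(
                f"need 0 <= n_drifts <= n_samples, got {n_drifts}/{n_samples}"
            )
        self.samples_analysed += n_samples
        self.drifts_accumulated += n_drifts

    def end_chunk(self) -> None:
        """One training step: compare the lifetime rate and move delta."""
        self.step_delta(self.drift_rate())

    # -- the standalone training loop -------------------------------------

    def train_on_chunk(
        self, detector: "AdwinDetector", chunk: Sequence[float] | Iterable[float]
    ) -> Tuple["DeltaController", "AdwinDetector"]:
        """Feed one chunk through a detector and take one delta step.

        Every element passes through ``detector.update`` at the current
        delta; the drift/sample counters accumulate over the stream
        lifetime; at chunk end a single ``step_delta`` is applied and the
        detector's delta is set to the new value for subsequent data.
        An empty chunk is a no-op.
        """
        chunk = list(chunk)
        if not chunk:
            return self, detector
        detector.delta = self.delta
        for value in chunk:
            drifted = detector.update(value)
            self.samples_analysed += 1
            if drifted:
                self.drifts_accumulated += 1
        self.end_chunk()
        detector.delta = self.delta
        return self, detector

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"DeltaController(delta={self.delta:g}, last_rate={self.last_rate:g}, "
            f"drifts={self.drifts_accumulated}, samples={self.samples_analysed})"
        )
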