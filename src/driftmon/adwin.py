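"""Streaming mean-change detection with an adaptive variable-length window.

The detector (an ADWIN-style adaptive windowing scheme) keeps every recent
sample in an explicit window.  After each arrival it considers every way of
splitting the window into an older subwindow ``W0`` and a newer subwindow
``W1`` and declares a concept drift as soon as the two subwindow means differ
by more than a confidence threshold.  On a drift the stale older part is
discarded — the retained window is exactly the former newer subwindow — and
the search repeats on the remainder until no further cut qualifies.

Two cut thresholds are provided:

``"bernstein"`` (default)
    The variance-adaptive bound of the canonical adaptive-windowing
    algorithm,

        eps = sqrt((2/m) * Var_W * ln(2/delta'))  +  (2/(3m)) * ln(2/delta')

    with ``m`` the harmonic mean of the subwindow sizes, ``Var_W`` the sample
    variance of the whole window and ``delta' = delta/n`` sharing the
    confidence over the ``n`` candidate splits.  The linear (range) term
    assumes data of order-one scale; feed standardised values.

``"hoeffding"``
    The simpler range-normalised Hoeffding form

        eps = sqrt((1/(2m)) * ln(4n/delta))

    valid for values confined to a unit range.  On unbounded noise it is far
    too permissive for extreme splits (a single large sample fires it), so it
    is not the default; it is kept because it is testable in closed form.

Higher ``delta`` makes the detector more sensitive (smaller thresholds);
``delta`` may be adapted between updates, e.g. by
:class:`driftmon.delta.DeltaController`.

The window is stored exactly (no bucket compression) and the cut search is
exhaustive, vectorised over all splits with prefix sums — O(n) per update.
This favours auditability over the logarithmic-memory approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AdwinDetector",
    "CutResult",
    "bernstein_threshold",
    "hoeffding_threshold",
]

_BOUNDS = ("bernstein", "hoeffding")


def _check_counts(n0: int, n1: int, n: int, delta: float) -> None:
    if n0 < 1 or n1 < 1:
        raise ValueError(f"subwindow sizes must be >= 1, got n0={n0}, n1={n1}")
    if n != n0 + n1:
        raise ValueError(f"n must equal n0 + n1, got n={n}, n0+n1={n0 + n1}")
    if not 0.0 < delta <= 1.0:
        raise ValueError(f"delta must be in (0, 1], got {delta}")


def hoeffding_threshold(n0: int, n1: int, n: int, delta: float) -> float:
    """Range-normalised Hoeffding cut threshold for unit-range data.

    ``eps = sqrt((1/(2m)) * ln(4n/delta))`` with ``m = 1/(1/n0 + 1/n1)``;
    the ``4n/delta`` term Bonferroni-shares the confidence across the ``n``
    candidate splits.  Strictly positive and deterministic.
    """
    _check_counts(n0, n1, n, delta)
    inv_m = 1.0 / n0 + 1.0 / n1
    return math.sqrt(0.5 * inv_m * math.log(4.0 * n / delta))


def bernstein_threshold(
    n0: int, n1: int, n: int, delta: float, variance: float
) -> float:
    """Variance-adaptive cut threshold (Bernstein-style bound).

    ``eps = sqrt((2/m) * variance * ln(2/d')) + (2/(3m)) * ln(2/d')`` with
    ``d' = delta/n`` and ``m`` the harmonic mean of the subwindow sizes.
    ``variance`` is the sample variance of the whole window.
    """
    _check_counts(n0, n1, n, delta)
    if variance < 0.0:
        raise ValueError(f"variance must be >= 0, got {variance}")
    inv_m = 1.0 / n0 + 1.0 / n1
    log_term = math.log(2.0 * n / delta)
    return math.sqrt(2.0 * inv_m * variance * log_term) + (2.0 / 3.0) * inv_m * log_term


@dataclass(frozen=True)
class CutResult:
    """Outcome of one exhaustive cut search over the current window.

    ``split_index`` is the number of elements in the older subwindow ``W0``
    (so ``1 <= split_index <= n-1`` when a cut is found); it is the *oldest*
    qualifying split, maximising the amount of stale data discarded.
    """

    cut_found: bool
    split_index: Optional[int] = None
    mean_w0: Optional[float] = None
    mean_w1: Optional[float] = None
    epsilon: Optional[float] = None


class AdwinDetector:
    """Adaptive-window drift detector over a univariate stream.

    Parameters
    ----------
    delta:
        Confidence in (0, 1]; higher values admit smaller deviations
        (more sensitive).  May be reassigned between updates.
    bound:
        ``"bernstein"`` (variance-adaptive, default) or ``"hoeffding"``.
    """

    def __init__(self, delta: float = 0.002, bound: str = "bernstein") -> None:
        if not 0.0 < delta <= 1.0:
            raise ValueError(f"delta must be in (0, 1], got {delta}")
        if bound not in _BOUNDS:
            raise ValueError(f"bound must be one of {_BOUNDS}, got {bound!r}")
        self._delta = float(delta)
        self.bound = bound
        self._window: list[float] = []
        self.total_seen = 0
        self.drifts_detected = 0

    # -- state ------------------------------------------------------------

    @property
    def delta(self) -> float:
        return self._delta

    @delta.setter
    def delta(self, value: float) -> None:
        if not 0.0 < value <= 1.0:
            raise ValueError(f"delta must be in (0, 1], got {value}")
        self._delta = float(value)

    @property
    def n(self) -> int:
        """Number of elements currently retained in the window."""
        return len(self._window)

    @property
    def elements(self) -> tuple[float, ...]:
        """Window contents, oldest first, newest last."""
        return tuple(self._window)

    @property
    def mean(self) -> float:
        return float(np.mean(self._window)) if self._window else 0.0

    # -- cut search -------------------------------------------------------

    def _search(self, arr: np.ndarray) -> CutResult:
        n = arr.size
        if n < 2:
            return CutResult(cut_found=False)
        csum = np.cumsum(arr)
        total = csum[-1]
        n0 = np.arange(1, n, dtype=np.float64)
        n1 = n - n0
        mean0 = csum[:-1] / n0
        mean1 = (total - csum[:-1]) / n1
        diff = np.abs(mean0 - mean1)
        inv_m = 1.0 / n0 + 1.0 / n1
        if self.bound == "hoeffding":
            eps = np.sqrt(0.5 * inv_m * math.log(4.0 * n / self._delta))
        else:
            var = float(np.var(arr, ddof=1))
            log_term = math.log(2.0 * n / self._delta)
            eps = np.sqrt(2.0 * inv_m * var * log_term) + (2.0 / 3.0) * inv_m * log_term
        hits = np.nonzero(diff >= eps)[0]
        if hits.size == 0:
            return CutResult(cut_found=False)
        i = int(hits[0])  # oldest qualifying split
        return CutResult(
            cut_found=True,
            split_index=i + 1,
            mean_w0=float(mean0[i]),
            mean_w1=float(mean1[i]),
            epsilon=float(eps[i]),
        )

    def find_cut(self) -> CutResult:
        """Search the current window for the oldest qualifying split.

        Does not mutate the window.  Returns ``cut_found=False`` for windows
        of fewer than two elements.
        """
        return self._search(np.asarray(self._window, dtype=np.float64))

    # -- streaming update -------------------------------------------------

    def update(self, value: float) -> bool:
        """Append one sample; return True iff a drift was detected.

        On drift, every element at or before the qualifying split is
        discarded and the search repeats on the remainder until no cut
        remains (one update may shrink the window several times).
        ``drifts_detected`` increments at most once per update.
        """
        v = float(value)
        if not math.isfinite(v):
            raise ValueError(f"non-finite sample value: {value!r}")
        self._window.append(v)
        self.total_seen += 1
        drifted = False
        while True:
            cut = self._search(np.asarray(self._window, dtype=np.float64))
            if not cut.cut_found:
                break
            # keep exactly the former newer subwindow, order preserved
            del self._window[: cut.split_index]
            drifted = True
        if drifted:
            self.drifts_detected += 1
        return drifted

    def update_many(self, values: Sequence[float]) -> list[int]:
        """Feed a sequence; return 0-based positions (within it) that drifted."""
        return [i for i, v in enumerate(values) if self.update(v)]

    def reset_window(self) -> None:
        self._window.clear()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"AdwinDetector(delta={self._delta:g}, bound={self.bound!r}, "
            f"n={self.n}, total_seen={self.total_seen}, "
            f"drifts={self.drifts_detected})"
        )
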