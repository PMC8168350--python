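"""Brute-force oracle for the adaptive-window detector.

Replays a stream while keeping the window as an explicit Python list and,
at every step, re-scanning *every* split of the stored window with a fresh
evaluation of the cut threshold.  Shares only the threshold formulas with
the implementation under test; the window bookkeeping, scan and truncation
logic are written independently here.
"""

import math

import numpy as np


def oracle_epsilons(n, delta, variance, bound):
    """Thresholds for all splits k = 1 .. n-1 of an n-element window."""
    k = np.arange(1, n, dtype=float)
    inv_m = 1.0 / k + 1.0 / (n - k)
    if bound == "hoeffding":
        return np.sqrt(0.5 * inv_m * np.log(4.0 * n / delta))
    log_term = math.log(2.0 * n / delta)
    return np.sqrt(2.0 * inv_m * variance * log_term) + (2.0 / 3.0) * inv_m * log_term


def oracle_scan(window, delta, bound):
    """Oldest split whose subwindow means differ by >= epsilon, else None."""
    n = len(window)
    if n < 2:
        return None
    arr = np.asarray(window, dtype=float)
    left_sums = np.cumsum(arr)[:-1]
    k = np.arange(1, n, dtype=float)
    mean_older = left_sums / k
    mean_newer = (arr.sum() - left_sums) / (n - k)
    variance = arr.var(ddof=1)
    eps = oracle_epsilons(n, delta, variance, bound)
    hits = np.flatnonzero(np.abs(mean_older - mean_newer) >= eps)
    return int(hits[0]) + 1 if hits.size else None


def oracle_replay(values, delta=0.002, bound="bernstein"):
    """Drift positions (0-based) and the final retained window."""
    window: list[float] = []
    positions: list[int] = []
    for i, value in enumerate(values):
        window.append(float(value))
        fired = False
        while True:
            split = oracle_scan(window, delta, bound)
            if split is None:
                break
            window = window[split:]
            fired = True
        if fired:
            positions.append(i)
    return positions, window
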