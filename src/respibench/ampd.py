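"""Automatic multiscale-based peak detection (AMPD).

AMPD locates peaks of quasi-periodic signals without amplitude thresholds: a
local-maxima scalogram is built over window scales k = 1..L (sample i is
"locally maximal at scale k" when it exceeds both neighbours k samples away),
the scale lambda with the most local maxima fixes the relevant row band, and
peaks are the samples that are maximal at every scale up to lambda.

This deterministic variant of the published method omits the random matrix
entries (they only break ties that the arg-max resolves anyway) and linearly
detrends each window first, which the scalogram construction assumes.
Complexity is O(n * L) per window, so the caller bounds L by the longest
plausible breath period.
"""

from __future__ import annotations

import numpy as np


def _local_maxima_scalogram(x: np.ndarray, max_scale: int) -> np.ndarray:
    n = len(x)
    m = np.zeros((max_scale, n), dtype=bool)
    for k in range(1, max_scale + 1):
        row = m[k - 1]
        row[k:n - k] = (x[k:n - k] > x[:n - 2 * k]) & (x[k:n - k] > x[2 * k:])
    return m


def ampd(x: np.ndarray, max_scale: int | None = None) -> np.ndarray:
    """Indices of the peaks of ``x`` (apply to ``-x`` for valleys).

    ``max_scale`` bounds the largest scale considered; the default is the
    textbook ceil(n/2) - 1, which is O(n^2) — callers working on long windows
    should pass half the longest expected period in samples.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        return np.empty(0, dtype=int)
    # remove linear trend so slow drift does not mask small-scale maxima
    t = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(t, x, 1)
    x = x - (slope * t + intercept)

    hard_cap = max(1, int(np.ceil(n / 2)) - 1)
    scale = min(max_scale or hard_cap, hard_cap)
    # antisymmetric padding so extrema near the window edges keep both
    # comparison neighbourhoods; without it every peak within lambda samples
    # of an edge is structurally undetectable, and even (mirror) padding
    # reflects an edge peak onto itself, defeating the strict comparison
    pad = min(scale, n - 1)
    xp = np.concatenate(
        [2 * x[0] - x[pad:0:-1], x, 2 * x[-1] - x[-2:-pad - 2:-1]])
    m = _local_maxima_scalogram(xp, scale)
    gamma = m.sum(axis=1)
    if gamma.max() == 0:
        return np.empty(0, dtype=int)  # monotone or constant signal
    lam = int(np.argmax(gamma)) + 1
    peaks = np.flatnonzero(m[:lam, pad:pad + n].all(axis=0))
    return peaks
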