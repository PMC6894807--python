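"""Stable-period segmentation from accelerometer frame energy (step 2).

Body movement contaminates every respiratory channel, so the night is first
segmented into movement-free ("stable") periods using the energy of the
accelerometer norm: 5 s frames with 50% overlap, an adaptive threshold found
as a slope change-point in the sorted energy array, and interval merging that
tolerates short (< 2 min) movement gaps.

The threshold procedure assumes the subject spends at least 25% of the
recording at rest, so the change-point scan starts a quarter of the way into
the slope array.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class FrameEnergy:
    """Per-frame energy of the accelerometer norm.

    ``energies[k] = sum(|s_k(i)|^2)`` over the k-th frame of
    ``frame_len_samples`` samples; frames hop by half a frame.
    """

    energies: np.ndarray
    frame_len_samples: int = 100
    hop_samples: int = 50
    fs: float = 20.0

    @property
    def frame_times(self) -> np.ndarray:
        """Frame centers, seconds."""
        starts = np.arange(len(self.energies)) * self.hop_samples
        return (starts + self.frame_len_samples / 2) / self.fs


@dataclass
class StablePeriods:
    """Disjoint, sorted [start_s, end_s) intervals kept for analysis."""

    intervals: list[tuple[float, float]]
    energy_threshold: float
    absorbed_gaps: list[tuple[float, float]] = field(default_factory=list)

    @property
    def total_s(self) -> float:
        return float(sum(e - s for s, e in self.intervals))

    def contains(self, t: float) -> bool:
        return any(s <= t < e for s, e in self.intervals)

    def to_json(self, path: str | Path) -> None:
        import json
        Path(path).write_text(json.dumps({
            "energy_threshold": self.energy_threshold,
            "intervals": [[round(s, 3), round(e, 3)] for s, e in self.intervals],
            "absorbed_gaps": [[round(s, 3), round(e, 3)] for s, e in self.absorbed_gaps],
        }, indent=1))

    def to_bed(self, path: str | Path) -> None:
        """3-column interval text file: start_s, end_s, label."""
        lines = [f"{s:.3f}\t{e:.3f}\tstable" for s, e in self.intervals]
        lines += [f"{s:.3f}\t{e:.3f}\tabsorbed_movement" for s, e in self.absorbed_gaps]
        Path(path).write_text("\n".join(sorted(lines, key=lambda l: float(l.split()[0]))) + "\n")


def frame_energy(
    accel_norm: np.ndarray, fs: float = 20.0,
    frame_len: int = 100, hop: int = 50,
) -> FrameEnergy:
    """Energy per 5 s frame (100 samples at 20 Hz), 50% overlap.

    The trailing partial frame is dropped.  A series shorter than one frame
    yields an empty FrameEnergy with a warning.
    """
    x = np.asarray(accel_norm, dtype=float)
    if len(x) < frame_len:
        log.warning("accelerometer series shorter than one %d-sample frame", frame_len)
        return FrameEnergy(np.empty(0), frame_len, hop, fs)
    n_frames = (len(x) - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    energies = np.sum(np.abs(x[idx]) ** 2, axis=1)
    return FrameEnergy(energies, frame_len, hop, fs)


def _resample_sorted(sorted_e: np.ndarray, n_out: int) -> np.ndarray:
    """Sorted energies resampled to exactly ``n_out`` points.

    Longer arrays: uniform nearest-rank index selection.  Shorter arrays
    (recordings under ~1.5 h): linear interpolation, logged, so the slope
    machinery downstream is unchanged.
    """
    n = len(sorted_e)
    if n >= n_out:
        idx = np.round(np.linspace(0, n - 1, n_out)).astype(int)
        return sorted_e[idx]
    log.info("only %d energy frames; interpolating sorted array up to %d", n, n_out)
    return np.interp(np.linspace(0, n - 1, n_out), np.arange(n), sorted_e)


@dataclass
class ThresholdDetails:
    """Intermediate products of the adaptive-threshold procedure."""

    sorted_resampled: np.ndarray   # 1080 sorted energies
    slopes: np.ndarray             # 359 regression slopes
    scan_start: int                # 90 for the default geometry
    change_index: int | None       # qualifying slope window, None if none
    threshold: float


def threshold_details(
    fe: FrameEnergy,
    *,
    n_resample: int = 1080,
    slope_window: int = 6,
    slope_hop: int = 3,
    slope_ratio: float = 5.8,
    min_sleep_fraction: float = 0.25,
) -> ThresholdDetails:
    """Adaptive movement/rest energy threshold.

    Procedure: sort energies ascending; resample to 1080 points; regress a
    slope on every 6 consecutive points with 50% overlap (359 slopes); scan
    from index 90 (= 359 * 25%, rounded) for the first slope exceeding 5.8x
    the running mean of all previous slopes; the threshold is the median of
    that window's 6 energy values.  If no slope qualifies the whole night is
    considered stable (threshold = max energy, with a warning).

    The procedure is scale-equivariant: scaling every energy by a positive
    factor scales the threshold by the same factor.
    """
    e = np.asarray(fe.energies, dtype=float)
    if len(e) < slope_window:
        raise ConfigurationError(
            f"need at least {slope_window} energy frames, got {len(e)}")
    arr = _resample_sorted(np.sort(e), n_resample)

    n_slopes = (n_resample - slope_window) // slope_hop + 1
    starts = slope_hop * np.arange(n_slopes)
    windows = arr[starts[:, None] + np.arange(slope_window)[None, :]]
    x = np.arange(slope_window, dtype=float)
    xc = x - x.mean()
    slopes = windows @ xc / (xc @ xc)          # least-squares slope per window

    scan_from = int(round(n_slopes * min_sleep_fraction))
    cum = np.cumsum(slopes)
    for i in range(scan_from, n_slopes):
        prev_mean = cum[i - 1] / i
        if prev_mean > 0 and slopes[i] > slope_ratio * prev_mean:
            return ThresholdDetails(arr, slopes, scan_from, i,
                                    float(np.median(windows[i])))
    log.warning("no slope change point found; whole night treated as stable")
    return ThresholdDetails(arr, slopes, scan_from, None, float(arr[-1]))


def adaptive_energy_threshold(fe: FrameEnergy, **kwargs) -> float:
    """The adaptive threshold alone; see :func:`threshold_details`."""
    return threshold_details(fe, **kwargs).threshold


def segment_stable_periods(
    fe: FrameEnergy, threshold: float, *, max_gap_s: float = 120.0,
) -> StablePeriods:
    """Merge below-threshold frames into stable intervals.

    Overlapping stable frames are combined; movement gaps shorter than
    ``max_gap_s`` between stable intervals are absorbed (and reported in
    ``absorbed_gaps``) to keep the polygraph signals contiguous.
    """
    if len(fe.energies) == 0:
        return StablePeriods([], threshold)
    stable = fe.energies < threshold
    frame_starts = np.arange(len(fe.energies)) * fe.hop_samples / fe.fs
    frame_len_s = fe.frame_len_samples / fe.fs

    intervals: list[list[float]] = []
    for k in np.flatnonzero(stable):
        s, e = frame_starts[k], frame_starts[k] + frame_len_s
        if intervals and s <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], e)
        else:
            intervals.append([s, e])

    merged: list[list[float]] = []
    gaps: list[tuple[float, float]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < max_gap_s:
            gaps.append((merged[-1][1], s))
            merged[-1][1] = e
        else:
            merged.append([s, e])
    # zero-length "gaps" from touching intervals are not movement
    gaps = [(s, e) for s, e in gaps if e - s > 0]
    return StablePeriods([(s, e) for s, e in merged], threshold, gaps)
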