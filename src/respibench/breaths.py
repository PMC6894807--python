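"""Breathing-cycle identification on the estimated nasal airflow (step 3).

Inspiratory peaks and expiratory valleys are found with AMPD in 3-minute
moving windows, envelopes are interpolated through them, and the excursion
(upper minus lower envelope) drives two regimes of onset detection:

* normal excursion — the breath onset is the expiratory-to-inspiratory
  zero crossing of the airflow between a valley and the following peak
  (falling back to the maximum-slope point when a DC offset prevents a
  crossing);
* highly reduced excursion (<= 35% of the 2-minute baseline for > 4 s) —
  airflow carries no usable onsets, so the valleys of the respiratory
  inductance band with the larger relative modulation stand in for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import find_peaks

from .ampd import ampd
from .errors import DataQualityError

log = logging.getLogger(__name__)


class OnsetSource(str, Enum):
    FLOW = "flow"
    RIP_THORAX = "rip_thorax"
    RIP_ABDOMEN = "rip_abdomen"


class CycleLabel(str, Enum):
    NORMAL = "normal"
    OA = "obstructive_apnea"
    CA = "central_apnea"
    OH = "obstructive_hypopnea"
    CH = "central_hypopnea"


@dataclass
class BreathCycle:
    """One respiratory cycle, onset-to-onset on the 20 Hz grid."""

    onset_s: float
    end_s: float
    insp_peak_s: float
    exp_valley_s: float
    amplitude: float                      # peak-to-valley flow excursion
    onset_source: OnsetSource = OnsetSource.FLOW
    label: CycleLabel = CycleLabel.NORMAL
    attempt_significant: bool | None = None  # filled for apneic cycles

    @property
    def ttot_s(self) -> float:
        return self.end_s - self.onset_s

    @property
    def obstructive(self) -> bool:
        return self.label in (CycleLabel.OA, CycleLabel.OH)


@dataclass
class ExcursionTrack:
    """Upper/lower airflow envelopes and their difference."""

    upper_env: np.ndarray
    lower_env: np.ndarray
    excursion: np.ndarray
    peaks: np.ndarray
    valleys: np.ndarray
    fs: float = 20.0


@dataclass
class ReducedSegment:
    """A highly-reduced-excursion interval, sample indices [start, end)."""

    start: int
    end: int
    baseline: float                       # pre-event 2-min mean excursion
    reference: OnsetSource | None = None
    attempts_detectable: bool = True


def _reconcile_alternation(
    flow: np.ndarray, peaks: np.ndarray, valleys: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Enforce strict peak/valley alternation.

    Two consecutive extrema of the same type mean the detector missed the
    opposite extremum between them; it is restored as the most extreme
    sample of the open interval.  When the pair is too close to hold one,
    the more extreme of the two is kept instead.
    """
    marks = sorted(
        [(int(i), 1) for i in peaks] + [(int(i), 0) for i in valleys])
    kept: list[tuple[int, int]] = []
    for i, kind in marks:
        if kept and kept[-1][1] == kind:
            j = kept[-1][0]
            if i - j >= 3:
                seg = flow[j + 1:i]
                k = j + 1 + int(np.argmin(seg) if kind == 1 else np.argmax(seg))
                kept.append((k, 1 - kind))
                kept.append((i, kind))
            else:
                better = flow[i] > flow[j] if kind == 1 else flow[i] < flow[j]
                if better:
                    kept[-1] = (i, kind)
        else:
            kept.append((i, kind))
    p = np.array([i for i, k in kept if k == 1], dtype=int)
    v = np.array([i for i, k in kept if k == 0], dtype=int)
    return p, v


def detect_peaks_valleys(
    flow: np.ndarray,
    fs: float = 20.0,
    *,
    window_s: float = 180.0,
    hop_s: float = 90.0,
    max_scale_s: float = 12.5,
    dedupe_s: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """AMPD peaks and valleys over 3-minute windows stitched at half-window
    hops; extrema within ``dedupe_s`` of an accepted one are dropped, and the
    final lists strictly alternate."""
    flow = np.asarray(flow, dtype=float)
    n = len(flow)
    if n == 0:
        return np.empty(0, int), np.empty(0, int)
    win = max(int(window_s * fs), 4)
    hop = max(int(hop_s * fs), 1)
    max_scale = max(int(max_scale_s * fs), 2)
    tol = max(int(dedupe_s * fs), 1)

    peaks: list[int] = []
    valleys: list[int] = []
    start = 0
    while True:
        stop = min(start + win, n)
        seg = flow[start:stop]
        for store, sig in ((peaks, seg), (valleys, -seg)):
            for i in ampd(sig, max_scale=max_scale):
                gi = int(i) + start
                if not store or gi - store[-1] > tol:
                    store.append(gi)
                elif gi != store[-1]:
                    # same extremum seen from two windows: keep first
                    pass
        if stop >= n:
            break
        start += hop
    p, v = np.array(sorted(set(peaks)), int), np.array(sorted(set(valleys)), int)
    return _reconcile_alternation(flow, p, v)


def rescue_missed_cycles(
    flow: np.ndarray,
    peaks: np.ndarray,
    valleys: np.ndarray,
    fs: float = 20.0,
    *,
    mean_amplitude: float,
    mean_ttot_s: float,
    amp_fraction: float = 0.2,
    gap_factor: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Recover cycles the multiscale detector missed.

    Gaps between consecutive peaks longer than ``gap_factor`` times the
    recent mean Ttot are scanned for zero-crossing oscillations whose
    amplitude exceeds ``amp_fraction`` of the recent mean cycle amplitude;
    qualifying oscillations are inserted as peak/valley pairs.
    """
    flow = np.asarray(flow, dtype=float)
    if len(peaks) < 2 or mean_ttot_s <= 0:
        return peaks, valleys
    gap_thr = gap_factor * mean_ttot_s * fs
    height = amp_fraction * mean_amplitude / 2.0  # half the peak-to-valley
    dist = max(int(0.5 * mean_ttot_s * fs), 1)

    new_p, new_v = list(peaks), list(valleys)
    for a, b in zip(peaks[:-1], peaks[1:]):
        if b - a <= gap_thr:
            continue
        seg = flow[a:b + 1]
        cand_p, _ = find_peaks(seg, height=height, distance=dist)
        cand_v, _ = find_peaks(-seg, height=height, distance=dist)
        # oscillation about zero: need both polarities present in the gap
        if len(cand_p) == 0 or len(cand_v) == 0:
            continue
        new_p.extend(int(i) + a for i in cand_p)
        new_v.extend(int(i) + a for i in cand_v)
    p = np.array(sorted(set(new_p)), int)
    v = np.array(sorted(set(new_v)), int)
    return _reconcile_alternation(flow, p, v)


def compute_excursion(
    flow: np.ndarray,
    peaks: np.ndarray,
    valleys: np.ndarray,
    fs: float = 20.0,
) -> ExcursionTrack:
    """Envelopes by shape-preserving (PCHIP) interpolation through peaks and
    valleys, constant-extrapolated at the edges; excursion clipped at 0."""
    flow = np.asarray(flow, dtype=float)
    if len(peaks) < 2 or len(valleys) < 2:
        raise DataQualityError(
            f"need >= 2 peaks and valleys for envelopes, got {len(peaks)}/{len(valleys)}")
    t = np.arange(len(flow))

    def env(idx: np.ndarray) -> np.ndarray:
        interp = PchipInterpolator(idx, flow[idx], extrapolate=False)
        out = interp(t)
        out[:idx[0]] = flow[idx[0]]
        out[idx[-1]:] = flow[idx[-1]]
        return out

    upper = env(peaks)
    lower = env(valleys)
    exc = np.clip(upper - lower, 0.0, None)
    return ExcursionTrack(upper, lower, exc, peaks, valleys, fs)


def segment_low_excursion(
    excursion: np.ndarray,
    fs: float,
    *,
    fraction: float,
    min_duration_s: float,
    max_duration_s: float | None = None,
    baseline_window_s: float = 120.0,
    min_baseline_s: float = 30.0,
) -> list[tuple[int, int, float]]:
    """Maximal intervals where excursion stays at or below ``fraction`` of
    the rolling pre-event baseline, with the stated duration bounds.

    The baseline is the mean excursion over (up to) the preceding
    ``baseline_window_s`` seconds, frozen while inside a candidate interval
    so a long event cannot erode its own reference.  Returns
    ``(start, end, baseline)`` sample triples.
    """
    exc = np.asarray(excursion, dtype=float)
    w = int(baseline_window_s * fs)
    min_n = int(min_baseline_s * fs)
    buf = np.zeros(w)
    buf_n = 0
    buf_i = 0
    buf_sum = 0.0
    out: list[tuple[int, int, float]] = []
    in_ev = False
    start = 0
    base_at = 0.0

    for i, v in enumerate(exc):
        if in_ev:
            if v > fraction * base_at:
                out.append((start, i, base_at))
                in_ev = False
        if not in_ev:
            baseline = buf_sum / buf_n if buf_n >= min_n else None
            if baseline is not None and baseline > 0 and v <= fraction * baseline:
                in_ev = True
                start = i
                base_at = baseline
            else:
                if buf_n < w:
                    buf[buf_i] = v
                    buf_sum += v
                    buf_n += 1
                else:
                    buf_sum += v - buf[buf_i]
                    buf[buf_i] = v
                buf_i = (buf_i + 1) % w
    if in_ev:
        out.append((start, len(exc), base_at))

    keep = []
    for s, e, b in out:
        dur = (e - s) / fs
        if dur <= min_duration_s:
            continue
        if max_duration_s is not None and dur > max_duration_s:
            continue
        keep.append((s, e, b))
    return keep


def find_reduced_excursion_segments(
    exc: ExcursionTrack,
    *,
    fraction: float = 0.35,
    min_duration_s: float = 4.0,
    baseline_window_s: float = 120.0,
) -> list[ReducedSegment]:
    """Highly-reduced airflow intervals: excursion <= 35% of the 2-minute
    pre-event baseline (a 65% reduction) lasting more than 4 seconds."""
    segs = segment_low_excursion(
        exc.excursion, exc.fs, fraction=fraction,
        min_duration_s=min_duration_s, baseline_window_s=baseline_window_s)
    return [ReducedSegment(s, e, b) for s, e, b in segs]


def _span(x: np.ndarray) -> float:
    return float(np.max(x) - np.min(x)) if len(x) else 0.0


def select_reference_rip(
    rip_thorax: np.ndarray,
    rip_abdomen: np.ndarray,
    segment: ReducedSegment,
    fs: float = 20.0,
    *,
    baseline_window_s: float = 120.0,
    flat_fraction: float = 0.08,
) -> tuple[OnsetSource, bool]:
    """Choose the effort band with the larger relative amplitude modulation
    during the reduced-airflow segment (ties go to the thorax).

    Modulation is the segment's peak-to-valley span normalized by the span
    over the 2 minutes before the segment.  If both bands are nearly flat
    (below ``flat_fraction`` of their baselines) no breathing attempts are
    detectable and the caller should treat the segment as central-type.
    """
    s, e = segment.start, segment.end
    pre = slice(max(0, s - int(baseline_window_s * fs)), s)
    ratios = {}
    for role, sig in ((OnsetSource.RIP_THORAX, rip_thorax),
                      (OnsetSource.RIP_ABDOMEN, rip_abdomen)):
        base = _span(sig[pre])
        ratios[role] = _span(sig[s:e]) / base if base > 0 else 0.0
    ref = (OnsetSource.RIP_THORAX
           if ratios[OnsetSource.RIP_THORAX] >= ratios[OnsetSource.RIP_ABDOMEN]
           else OnsetSource.RIP_ABDOMEN)
    detectable = ratios[ref] >= flat_fraction
    return ref, detectable


def _rip_valleys(
    rip: np.ndarray, segment: ReducedSegment, fs: float,
    baseline_window_s: float = 120.0, min_spacing_s: float = 1.0,
    prominence_fraction: float = 0.08,
) -> np.ndarray:
    """Valley sample indices of the reference RIP band inside a segment."""
    s, e = segment.start, segment.end
    pre = slice(max(0, s - int(baseline_window_s * fs)), s)
    prom = prominence_fraction * max(_span(rip[pre]), 1e-12)
    v, _ = find_peaks(-rip[s:e], distance=max(int(min_spacing_s * fs), 1),
                      prominence=prom)
    return v + s


def detect_breath_onsets(
    flow: np.ndarray,
    exc: ExcursionTrack,
    rip_thorax: np.ndarray,
    rip_abdomen: np.ndarray,
    reduced_segments: list[ReducedSegment],
    fs: float = 20.0,
    *,
    t0: float = 0.0,
    dedupe_s: float = 0.25,
    min_ttot_s: float = 1.0,
) -> list[BreathCycle]:
    """Assemble the onset train and build onset-to-onset cycles.

    Outside reduced segments each onset is the last negative-to-positive
    airflow crossing between a valley and the following peak (max first
    derivative if no crossing exists).  Inside reduced segments onsets come
    from the reference RIP band's valleys.  ``t0`` offsets the returned
    times, so callers can analyze one stable period at a time.
    """
    flow = np.asarray(flow, dtype=float)
    n = len(flow)
    if n == 0:
        return []
    in_reduced = np.zeros(n, dtype=bool)
    for seg in reduced_segments:
        in_reduced[seg.start:seg.end] = True

    onsets: list[tuple[int, OnsetSource]] = []
    for v in exc.valleys:
        nxt = exc.peaks[exc.peaks > v]
        if len(nxt) == 0:
            continue
        p = int(nxt[0])
        if in_reduced[v]:
            continue
        seg = flow[v:p + 1]
        cross = np.flatnonzero((seg[:-1] <= 0) & (seg[1:] > 0))
        if len(cross):
            onsets.append((int(v + cross[-1] + 1), OnsetSource.FLOW))
        elif p - v >= 2:
            onsets.append(
                (int(v + np.argmax(np.diff(seg)) + 1), OnsetSource.FLOW))

    for seg in reduced_segments:
        ref, detectable = select_reference_rip(
            rip_thorax, rip_abdomen, seg, fs)
        seg.reference = ref
        seg.attempts_detectable = detectable
        if not detectable:
            continue
        rip = rip_thorax if ref is OnsetSource.RIP_THORAX else rip_abdomen
        for i in _rip_valleys(rip, seg, fs):
            onsets.append((int(i), ref))

    onsets.sort(key=lambda t: t[0])
    # onsets closer than a plausible cycle (e.g. a flow crossing and a RIP
    # valley marking the same breath at a segment boundary) are duplicates;
    # the later one is dropped
    tol = max(int(max(dedupe_s, min_ttot_s) * fs), 1)
    cleaned: list[tuple[int, OnsetSource]] = []
    for i, src in onsets:
        if cleaned and i - cleaned[-1][0] <= tol:
            continue
        cleaned.append((i, src))

    cycles: list[BreathCycle] = []
    for (i, src), (j, _) in zip(cleaned[:-1], cleaned[1:]):
        window = flow[i:j]
        if len(window) == 0:
            continue
        pk = i + int(np.argmax(window))
        vl = i + int(np.argmin(window))
        cycles.append(BreathCycle(
            onset_s=t0 + i / fs,
            end_s=t0 + j / fs,
            insp_peak_s=t0 + pk / fs,
            exp_valley_s=t0 + vl / fs,
            amplitude=float(np.max(window) - np.min(window)),
            onset_source=src,
        ))
    return cycles
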