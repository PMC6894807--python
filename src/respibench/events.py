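"""Sleep-disordered-breathing event scoring (steps 4-5).

Apneas and hypopneas are detected on the nasal-airflow excursion and
classified as obstructive or central:

* apnea — excursion at or below ``sqrt(0.10) ~ 31.6%`` of the 2-minute
  baseline (the AASM >= 90% drop, transposed from the nasal-pressure scale to
  the square-root flow scale), 10-180 s, confirmed by a > 20% drop of a
  second flow channel (thermistance if present, else RIP flow) against its
  1-minute pre/post baselines.  Obstructive when at least one breathing
  attempt in the reference effort band reaches 10% of its baseline
  excursion, central otherwise.
* hypopnea — excursion reduction >= 30% (but above the apnea level),
  10-180 s, confirmed by a >= 10% drop of the secondary channel.
  Obstructive when snoring, thoracoabdominal paradox, or a flattened
  (flow-limited) inspiratory shape accompanies any cycle of the event,
  central when none does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import find_peaks

from .breaths import (
    BreathCycle, CycleLabel, ExcursionTrack, OnsetSource, ReducedSegment,
    segment_low_excursion, select_reference_rip,
)
from .errors import DataQualityError

log = logging.getLogger(__name__)

APNEA_KINDS = (CycleLabel.OA, CycleLabel.CA)
HYPOPNEA_KINDS = (CycleLabel.OH, CycleLabel.CH)


@dataclass
class SDBEvent:
    """One scored apnea or hypopnea."""

    onset_s: float
    duration_s: float
    kind: CycleLabel | None = None
    attempts: list[tuple[float, bool]] = field(default_factory=list)
    evidence: set[str] = field(default_factory=set)
    baseline_excursion: float = 0.0
    confirmed: bool = True

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    @property
    def is_apnea(self) -> bool:
        return self.kind in APNEA_KINDS


@dataclass
class IFLFeatures:
    """Shape descriptors of one inspiratory flow limb."""

    peak_count: int
    norm_peak_amp: float
    scooping_index: float
    kurtosis: float
    deviation_index: float
    flattening_index: float
    skewness: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([
            self.peak_count, self.norm_peak_amp, self.scooping_index,
            self.kurtosis, self.deviation_index, self.flattening_index,
            self.skewness,
        ], dtype=float)


# ---------------------------------------------------------------------------
# detection


def _confirmation_drop(
    confirm_exc: np.ndarray, start: int, end: int, fs: float,
    window_s: float = 60.0,
) -> float:
    """Fractional drop of the confirmation-channel excursion inside the
    event versus its 1-minute pre- and post-event baselines."""
    w = int(window_s * fs)
    pre = confirm_exc[max(0, start - w):start]
    post = confirm_exc[end:end + w]
    ref = np.concatenate([pre, post])
    if len(ref) == 0 or np.mean(ref) <= 0:
        return 0.0
    return 1.0 - float(np.mean(confirm_exc[start:end]) / np.mean(ref))


def detect_apneas(
    exc: ExcursionTrack,
    confirm_exc: np.ndarray | None,
    *,
    excursion_fraction: float = 0.3162,
    min_duration_s: float = 10.0,
    max_duration_s: float = 180.0,
    baseline_window_s: float = 120.0,
    confirm_window_s: float = 60.0,
    confirm_drop: float = 0.20,
    allow_unconfirmed: bool = False,
    t0: float = 0.0,
) -> list[SDBEvent]:
    """Apnea candidates on the airflow excursion, kind left unset.

    Without a confirmation channel the candidates are flagged unconfirmed
    and, unless ``allow_unconfirmed`` (a flow-only trace such as the bench
    pneumotachograph), excluded.
    """
    segs = segment_low_excursion(
        exc.excursion, exc.fs, fraction=excursion_fraction,
        min_duration_s=min_duration_s, max_duration_s=max_duration_s,
        baseline_window_s=baseline_window_s)
    events: list[SDBEvent] = []
    for s, e, baseline in segs:
        ev = SDBEvent(onset_s=t0 + s / exc.fs, duration_s=(e - s) / exc.fs,
                      baseline_excursion=baseline)
        if confirm_exc is None:
            ev.confirmed = False
            if not allow_unconfirmed:
                log.info("apnea candidate at %.1f s dropped: no confirmation channel",
                         ev.onset_s)
                continue
        else:
            drop = _confirmation_drop(confirm_exc, s, e, exc.fs, confirm_window_s)
            if drop <= confirm_drop:
                continue  # likely mouth breathing, not a true apnea
        events.append(ev)
    return events


def detect_hypopneas(
    exc: ExcursionTrack,
    confirm_exc: np.ndarray | None,
    apneas: list[SDBEvent],
    *,
    excursion_fraction: float = 0.70,
    min_duration_s: float = 10.0,
    max_duration_s: float = 180.0,
    baseline_window_s: float = 120.0,
    confirm_window_s: float = 60.0,
    confirm_drop: float = 0.10,
    allow_unconfirmed: bool = False,
    t0: float = 0.0,
) -> list[SDBEvent]:
    """Hypopnea candidates (>= 30% excursion reduction), apnea intervals
    excluded from candidacy, kind left unset."""
    segs = segment_low_excursion(
        exc.excursion, exc.fs, fraction=excursion_fraction,
        min_duration_s=min_duration_s, max_duration_s=max_duration_s,
        baseline_window_s=baseline_window_s)
    events: list[SDBEvent] = []
    for s, e, baseline in segs:
        onset = t0 + s / exc.fs
        end = t0 + e / exc.fs
        overlap = sum(
            max(0.0, min(end, a.end_s) - max(onset, a.onset_s)) for a in apneas)
        if overlap > 0.5 * (end - onset):
            continue  # this reduction is (mostly) an apnea
        ev = SDBEvent(onset_s=onset, duration_s=end - onset,
                      baseline_excursion=baseline)
        if confirm_exc is None:
            ev.confirmed = False
            if not allow_unconfirmed:
                continue
        else:
            drop = _confirmation_drop(confirm_exc, s, e, exc.fs, confirm_window_s)
            if drop < confirm_drop:
                continue
        events.append(ev)
    return events


# ---------------------------------------------------------------------------
# apnea classification


def classify_apnea(
    event: SDBEvent,
    rip_ref: np.ndarray,
    rip_exc: np.ndarray,
    fs: float = 20.0,
    *,
    significance: float = 0.10,
    confirm_window_s: float = 60.0,
    t0: float = 0.0,
    min_attempt_spacing_s: float = 1.0,
) -> SDBEvent:
    """Score breathing attempts in the reference effort band and set the kind.

    An attempt is a RIP peak inside the event; it is significant when the RIP
    excursion at the peak time reaches ``significance`` (10%) of the 1-minute
    pre+post excursion baseline.  Any significant attempt makes the event
    obstructive (mixed events count as obstructive); none makes it central.
    """
    s = int((event.onset_s - t0) * fs)
    e = int((event.end_s - t0) * fs)
    s, e = max(0, s), min(len(rip_ref), e)
    w = int(confirm_window_s * fs)
    ref = np.concatenate([rip_exc[max(0, s - w):s], rip_exc[e:e + w]])
    baseline = float(np.mean(ref)) if len(ref) else 0.0

    seg = rip_ref[s:e]
    attempts: list[tuple[float, bool]] = []
    if len(seg) >= 3 and baseline > 0:
        span = float(np.max(seg) - np.min(seg))
        peaks, _ = find_peaks(
            seg, distance=max(int(min_attempt_spacing_s * fs), 1),
            prominence=0.02 * max(span, baseline))
        for p in peaks:
            t = t0 + (s + int(p)) / fs
            significant = rip_exc[s + int(p)] >= significance * baseline
            attempts.append((t, bool(significant)))
    event.attempts = attempts
    event.kind = (CycleLabel.OA
                  if any(sig for _, sig in attempts) else CycleLabel.CA)
    return event


# ---------------------------------------------------------------------------
# hypopnea obstruction evidence


def _insp_slice(flow: np.ndarray, cycle: BreathCycle, fs: float, t0: float
                ) -> tuple[int, int, int]:
    """(start, insp_end, end) sample indices of a cycle; inspiration runs
    from the onset to the first non-positive flow sample after the
    inspiratory peak."""
    i = int(round((cycle.onset_s - t0) * fs))
    j = int(round((cycle.end_s - t0) * fs))
    i, j = max(0, i), min(len(flow), j)
    pk = min(max(int(round((cycle.insp_peak_s - t0) * fs)), i), j - 1)
    k = pk
    while k < j and flow[k] > 0:
        k += 1
    return i, max(k, i + 1), j


def detect_snore(
    audio: np.ndarray,
    flow: np.ndarray,
    cycle: BreathCycle,
    fs: float = 20.0,
    *,
    power_ratio: float = 2.0,
    t0: float = 0.0,
) -> bool:
    """Snoring: inspiratory audio power exceeds expiratory power by
    ``power_ratio`` within the cycle."""
    i, k, j = _insp_slice(flow, cycle, fs, t0)
    insp = np.clip(audio[i:k], 0.0, None)
    exp = np.clip(audio[k:j], 0.0, None)
    if len(insp) == 0 or len(exp) == 0:
        return False
    exp_mean = float(np.mean(exp))
    insp_mean = float(np.mean(insp))
    if exp_mean <= 0:
        return insp_mean > 0
    return insp_mean > power_ratio * exp_mean


def detect_paradox(
    rip_thorax: np.ndarray,
    rip_abdomen: np.ndarray,
    cycle: BreathCycle,
    fs: float = 20.0,
    *,
    t0: float = 0.0,
) -> bool:
    """Thoracoabdominal paradox: within the cycle, the thorax peak is closer
    in time to the abdomen valley than to the abdomen peak."""
    i = int(round((cycle.onset_s - t0) * fs))
    j = int(round((cycle.end_s - t0) * fs))
    i, j = max(0, i), min(len(rip_thorax), j)
    th, ab = rip_thorax[i:j], rip_abdomen[i:j]
    if len(th) < 3 or np.ptp(th) == 0 or np.ptp(ab) == 0:
        log.debug("paradox check skipped at %.1f s: missing extrema", cycle.onset_s)
        return False
    tp = int(np.argmax(th))
    ap = int(np.argmax(ab))
    av = int(np.argmin(ab))
    return abs(tp - av) < abs(tp - ap)


def extract_ifl_features(
    insp_flow: np.ndarray, baseline_amp: float,
) -> IFLFeatures:
    """Seven shape features of one inspiratory limb.

    Local definitions: scooping = 1 - (mean over the middle 50% of
    inspiration)/peak; flattening = fraction of the limb within 15% of the
    peak; deviation = RMS residual from the least-squares half-sine,
    normalized by the peak; kurtosis/skewness are the standardized moments
    of the flow-versus-time curve.
    """
    x = np.asarray(insp_flow, dtype=float)
    peak = float(np.max(x)) if len(x) else 0.0
    if len(x) < 8 or peak <= 0:
        log.debug("degenerate inspiration (%d samples)", len(x))
        return IFLFeatures(0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    n = len(x)
    pk_idx, _ = find_peaks(x, prominence=0.1 * peak)
    peak_count = max(len(pk_idx), 1)
    mid = x[n // 4: n - n // 4]
    scooping = 1.0 - float(np.mean(mid)) / peak
    half_sine = np.sin(np.pi * np.arange(n) / (n - 1))
    coef = float(x @ half_sine / (half_sine @ half_sine))
    deviation = float(np.sqrt(np.mean((x - coef * half_sine) ** 2))) / peak
    flattening = float(np.mean(x >= 0.85 * peak))
    kurt = float(stats.kurtosis(x))
    skew = float(stats.skew(x))
    norm_amp = peak / baseline_amp if baseline_amp > 0 else 0.0
    f = IFLFeatures(peak_count, norm_amp, scooping, kurt, deviation,
                    flattening, skew)
    if not np.all(np.isfinite(f.as_array())):
        return IFLFeatures(0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    return f


class IFLModel:
    """Flow-limitation classifier: a 7-14-14-1 sigmoid network.

    Thin wrapper over scikit-learn's MLPClassifier with the fixed
    architecture; ``predict_flag`` thresholds the sigmoid output at 0.5.
    """

    def __init__(self) -> None:
        self._clf = None

    @property
    def trained(self) -> bool:
        return self._clf is not None

    def fit(self, features: np.ndarray, labels: np.ndarray, seed: int = 42
            ) -> "IFLModel":
        from sklearn.neural_network import MLPClassifier

        labels = np.asarray(labels).astype(int)
        classes, counts = np.unique(labels, return_counts=True)
        if len(classes) < 2:
            raise ValueError("IFL training corpus must contain both classes")
        if counts.max() > 10 * counts.min():
            raise ValueError(
                f"IFL class imbalance {counts.max()}:{counts.min()} exceeds 10:1")
        clf = MLPClassifier(
            hidden_layer_sizes=(14, 14), activation="logistic",
            solver="adam", max_iter=3000, random_state=seed)
        clf.fit(np.asarray(features, float), labels)
        self._clf = clf
        return self

    def predict_flag(self, features: IFLFeatures) -> bool:
        if self._clf is None:
            raise RuntimeError(
                "IFL model is untrained; call train_ifl_model first")
        if features.degenerate:
            return False
        prob = self._clf.predict_proba(features.as_array()[None, :])[0, 1]
        return bool(prob > 0.5)


def train_ifl_model(
    features: np.ndarray, labels: np.ndarray, seed: int = 42,
) -> IFLModel:
    """Train the flow-limitation network on a labelled feature corpus."""
    return IFLModel().fit(features, labels, seed)


def classify_ifl(features: IFLFeatures, model: IFLModel) -> bool:
    """True when the inspiratory limb is flow-limited (network output > 0.5)."""
    return model.predict_flag(features)


def classify_hypopnea(
    event: SDBEvent, cycle_evidence: list[set[str]],
) -> SDBEvent:
    """Obstructive when snoring, paradox or flow limitation is present on any
    cycle of the event; otherwise central.  The union of observed criteria is
    recorded as the event's evidence."""
    evidence: set[str] = set()
    for ev in cycle_evidence:
        evidence |= ev
    event.evidence = evidence
    event.kind = CycleLabel.OH if evidence else CycleLabel.CH
    return event


# ---------------------------------------------------------------------------
# summaries


def label_cycles(cycles: list[BreathCycle], events: list[SDBEvent]) -> None:
    """Assign each event's kind to the cycles it covers.

    A cycle belongs to an event when at least half of the cycle overlaps it,
    so a cycle straddling the event end (where breathing has already
    recovered) keeps its normal label and is replayed as recorded.
    """
    for ev in events:
        if ev.kind is None:
            continue
        sig_times = [t for t, sig in ev.attempts if sig]
        for c in cycles:
            overlap = min(ev.end_s, c.end_s) - max(ev.onset_s, c.onset_s)
            if overlap >= 0.5 * c.ttot_s:
                c.label = ev.kind
                if ev.is_apnea:
                    c.attempt_significant = any(
                        c.onset_s <= t < c.end_s for t in sig_times)


def event_indices(events: list[SDBEvent], stable_hours: float) -> dict[str, float]:
    """AHI / AI / HI in events per stable hour."""
    if stable_hours <= 0:
        raise DataQualityError("no stable time to normalize event indices")
    n_a = sum(1 for e in events if e.kind in APNEA_KINDS)
    n_h = sum(1 for e in events if e.kind in HYPOPNEA_KINDS)
    return {
        "ahi": (n_a + n_h) / stable_hours,
        "ai": n_a / stable_hours,
        "hi": n_h / stable_hours,
        "n_apneas": float(n_a),
        "n_hypopneas": float(n_h),
        "stable_hours": stable_hours,
    }


__all__ = [
    "SDBEvent", "IFLFeatures", "IFLModel", "detect_apneas", "detect_hypopneas",
    "classify_apnea", "classify_hypopnea", "detect_snore", "detect_paradox",
    "extract_ifl_features", "train_ifl_model", "classify_ifl", "label_cycles",
    "event_indices", "ReducedSegment", "select_reference_rip",
]
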