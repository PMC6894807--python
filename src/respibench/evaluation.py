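"""Agreement between the recorded airflow and its bench replay.

Cycle-by-cycle statistics mirror the bench-validation analyses: relative
peak-to-valley amplitude and Ttot bias (mean, SD, 2.5/50/97.5 percentiles,
the same after trimming to the central 95%, linear regression and
Bland–Altman limits), per-cycle Pearson correlation of the waveforms split
by obstruction, and apnea-level sensitivity/PPV with onset and duration
agreement.

Relative amplitude normalizes each cycle by its own trace's 2-minute rolling
baseline amplitude, so a bench trace is compared against its own scale just
as the source is.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .breaths import BreathCycle
from .errors import DataQualityError
from .events import SDBEvent

log = logging.getLogger(__name__)


@dataclass
class AgreementStats:
    """Bias statistics for one paired quantity."""

    mean: float = float("nan")
    sd: float = float("nan")
    p2_5: float = float("nan")
    median: float = float("nan")
    p97_5: float = float("nan")
    trimmed_mean: float = float("nan")
    trimmed_sd: float = float("nan")
    regression_slope: float = float("nan")
    regression_intercept: float = float("nan")
    loa_low: float = float("nan")
    loa_high: float = float("nan")
    n: int = 0


@dataclass
class EvaluationReport:
    amplitude_pct: AgreementStats = field(default_factory=AgreementStats)
    ttot_s: AgreementStats = field(default_factory=AgreementStats)
    pearson_unobstructed: tuple[float, float] = (float("nan"), float("nan"))
    pearson_obstructed: tuple[float, float] = (float("nan"), float("nan"))
    n_correlation_excluded: int = 0
    apnea_sensitivity: float = float("nan")
    apnea_ppv: float = float("nan")
    onset_diff_mean_s: float = float("nan")
    onset_diff_sd_s: float = float("nan")
    duration_bias: AgreementStats = field(default_factory=AgreementStats)
    n_cycles: int = 0
    n_apneas_source: int = 0
    n_apneas_bench: int = 0
    n_apneas_matched: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))
        text = json.dumps(dataclasses.asdict(self), default=enc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------


def match_cycles(
    source_cycles: list[BreathCycle],
    bench_cycles: list[BreathCycle],
    tolerance_s: float = 1.5,
) -> list[tuple[int, int]]:
    """Greedy nearest-onset pairing within ``tolerance_s``; each cycle is
    used at most once.  Returns index pairs into the two (onset-sorted)
    lists."""
    pairs: list[tuple[int, int]] = []
    j = 0
    used: set[int] = set()
    for i, sc in enumerate(source_cycles):
        while j < len(bench_cycles) and bench_cycles[j].onset_s < sc.onset_s - tolerance_s:
            j += 1
        best, best_d = None, tolerance_s
        for k in range(j, len(bench_cycles)):
            d = abs(bench_cycles[k].onset_s - sc.onset_s)
            if bench_cycles[k].onset_s > sc.onset_s + tolerance_s:
                break
            if k not in used and d <= best_d:
                best, best_d = k, d
        if best is not None:
            used.add(best)
            pairs.append((i, best))
    return pairs


def relative_amplitudes(
    cycles: list[BreathCycle], window_s: float = 120.0,
) -> np.ndarray:
    """Per-cycle amplitude normalized by the trace's own rolling baseline:
    the median amplitude of the cycles in the preceding 2 minutes (global
    median when no history exists yet).

    The median keeps the baseline anchored to unobstructed breathing even
    when the window contains an apnea — the few near-zero cycles there would
    otherwise drag a mean baseline down and inflate every relative amplitude
    for the following two minutes.
    """
    amps = np.array([c.amplitude for c in cycles], dtype=float)
    onsets = np.array([c.onset_s for c in cycles], dtype=float)
    overall = float(np.median(amps)) if len(amps) else 1.0
    out = np.empty(len(cycles))
    lo = 0
    for i, t in enumerate(onsets):
        while onsets[lo] < t - window_s:
            lo += 1
        hist = amps[lo:i]
        base = float(np.median(hist)) if len(hist) >= 3 else overall
        out[i] = amps[i] / base if base > 0 else 0.0
    return out


def _stats_for(bias: np.ndarray, x: np.ndarray, y: np.ndarray) -> AgreementStats:
    p_lo, med, p_hi = np.percentile(bias, [2.5, 50.0, 97.5])
    inside = (bias >= p_lo) & (bias <= p_hi)
    if not inside.any():       # tiny samples: the band can exclude everything
        inside[:] = True
    if len(np.unique(x)) > 1:
        reg = stats.linregress(x, y)
        slope, intercept = float(reg.slope), float(reg.intercept)
    else:
        slope, intercept = float("nan"), float("nan")
    mean = float(np.mean(bias))
    sd = float(np.std(bias, ddof=1)) if len(bias) > 1 else 0.0
    return AgreementStats(
        mean=mean, sd=sd,
        p2_5=float(p_lo), median=float(med), p97_5=float(p_hi),
        trimmed_mean=float(np.mean(bias[inside])),
        trimmed_sd=float(np.std(bias[inside], ddof=1)) if inside.sum() > 1 else 0.0,
        regression_slope=slope, regression_intercept=intercept,
        loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd,
        n=len(bias))


def amplitude_ttot_agreement(
    source_cycles: list[BreathCycle],
    bench_cycles: list[BreathCycle],
    pairs: list[tuple[int, int]],
    report: EvaluationReport | None = None,
    *,
    baseline_window_s: float = 120.0,
) -> EvaluationReport:
    """Relative-amplitude (percentage points) and Ttot (seconds) bias
    statistics over the matched pairs; bias is bench minus source."""
    if len(pairs) < 2:
        raise DataQualityError("need at least 2 matched cycle pairs")
    report = report or EvaluationReport()
    rel_s = relative_amplitudes(source_cycles, baseline_window_s)
    rel_b = relative_amplitudes(bench_cycles, baseline_window_s)
    i_s = np.array([i for i, _ in pairs])
    i_b = np.array([j for _, j in pairs])
    a_s, a_b = rel_s[i_s] * 100.0, rel_b[i_b] * 100.0
    report.amplitude_pct = _stats_for(a_b - a_s, a_s, a_b)
    t_s = np.array([source_cycles[i].ttot_s for i in i_s])
    t_b = np.array([bench_cycles[j].ttot_s for j in i_b])
    report.ttot_s = _stats_for(t_b - t_s, t_s, t_b)
    report.n_cycles = len(pairs)
    return report


def morphology_correlation(
    source_cycles: list[BreathCycle],
    bench_cycles: list[BreathCycle],
    pairs: list[tuple[int, int]],
    flow_source: np.ndarray,
    flow_bench: np.ndarray,
    fs: float = 20.0,
    *,
    t0_source: float = 0.0,
    t0_bench: float = 0.0,
    min_samples: int = 40,
    report: EvaluationReport | None = None,
) -> EvaluationReport:
    """Per-pair Pearson r of the cycle waveforms, resampled to the shorter
    cycle's length, reported as mean +/- SD separately for cycles with and
    without upper-airway obstruction.  Cycles shorter than ``min_samples``
    or with zero variance are excluded and counted."""
    report = report or EvaluationReport()
    r_obs: list[float] = []
    r_un: list[float] = []
    excluded = 0

    def cut(flow: np.ndarray, c: BreathCycle, t0: float) -> np.ndarray:
        i = int(round((c.onset_s - t0) * fs))
        j = int(round((c.end_s - t0) * fs))
        return flow[max(0, i):min(len(flow), j)]

    for i, j in pairs:
        a = cut(flow_source, source_cycles[i], t0_source)
        b = cut(flow_bench, bench_cycles[j], t0_bench)
        if min(len(a), len(b)) < min_samples:
            excluded += 1
            continue
        m = min(len(a), len(b))
        if len(a) != m:
            a = np.interp(np.linspace(0, len(a) - 1, m), np.arange(len(a)), a)
        if len(b) != m:
            b = np.interp(np.linspace(0, len(b) - 1, m), np.arange(len(b)), b)
        if np.std(a) == 0 or np.std(b) == 0:
            excluded += 1
            log.debug("zero-variance cycle pair at %.1f s skipped",
                      source_cycles[i].onset_s)
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        (r_obs if source_cycles[i].obstructive else r_un).append(r)

    def summarize(rs: list[float]) -> tuple[float, float]:
        if not rs:
            return float("nan"), float("nan")
        return (float(np.mean(rs)),
                float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0)

    report.pearson_unobstructed = summarize(r_un)
    report.pearson_obstructed = summarize(r_obs)
    report.n_correlation_excluded = excluded
    return report


def apnea_agreement(
    source_events: list[SDBEvent],
    bench_events: list[SDBEvent],
    *,
    overlap_fraction: float = 0.5,
    report: EvaluationReport | None = None,
) -> EvaluationReport:
    """Apnea correspondence between the two traces.

    Events match when their intervals overlap by at least half the shorter
    event.  Sensitivity = matched / source apneas, PPV = matched / bench
    apneas; both are 1 by convention when neither trace has apneas.  Onset
    differences and duration bias (bench minus source) are summarized over
    the matched pairs.
    """
    report = report or EvaluationReport()
    src = [e for e in source_events if e.is_apnea or e.kind is None]
    ben = [e for e in bench_events if e.is_apnea or e.kind is None]
    used: set[int] = set()
    matches: list[tuple[SDBEvent, SDBEvent]] = []
    for e in src:
        best, best_ov = None, 0.0
        for k, b in enumerate(ben):
            if k in used:
                continue
            ov = min(e.end_s, b.end_s) - max(e.onset_s, b.onset_s)
            need = overlap_fraction * min(e.duration_s, b.duration_s)
            if ov >= need and ov > best_ov:
                best, best_ov = k, ov
        if best is not None:
            used.add(best)
            matches.append((e, ben[best]))

    report.n_apneas_source = len(src)
    report.n_apneas_bench = len(ben)
    report.n_apneas_matched = len(matches)
    report.apnea_sensitivity = len(matches) / len(src) if src else 1.0
    report.apnea_ppv = len(matches) / len(ben) if ben else 1.0
    if matches:
        onset_d = np.array([b.onset_s - e.onset_s for e, b in matches])
        report.onset_diff_mean_s = float(np.mean(onset_d))
        report.onset_diff_sd_s = (
            float(np.std(onset_d, ddof=1)) if len(onset_d) > 1 else 0.0)
        dur_s = np.array([e.duration_s for e, _ in matches])
        dur_b = np.array([b.duration_s for _, b in matches])
        report.duration_bias = _stats_for(dur_b - dur_s, dur_s, dur_b)
    return report
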