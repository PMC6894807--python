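"""End-to-end orchestration: record -> cycles/events -> commands -> replay
-> agreement report.

Each stable period is analyzed independently (baselines never straddle a
movement gap); results are concatenated on the recording timebase.  The
bench trace is re-analyzed through a flow-only variant of the same breath
and apnea machinery — a pneumotachograph trace has no effort bands, so
reduced-excursion periods yield no onsets there and apneas are scored
without a confirmation channel, exactly as one would score the physical
bench output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from . import breaths as br
from . import events as ev
from .commands import (
    BenchCommandSet, LungModel, StarlingCalibration, StarlingModel,
    build_commands, calibrate_starling,
)
from .config import PipelineConfig
from .evaluation import (
    EvaluationReport, amplitude_ttot_agreement, apnea_agreement,
    match_cycles, morphology_correlation,
)
from .events import IFLModel, SDBEvent
from .io_polygraph import PolygraphRecord
from .stability import (
    StablePeriods, adaptive_energy_threshold, frame_energy,
    segment_stable_periods,
)
from .virtual_bench import BenchTrace, run_bench

log = logging.getLogger(__name__)


@lru_cache(maxsize=4)
def get_ifl_model(seed: int = 42) -> IFLModel:
    """The flow-limitation network, trained once per seed on the synthetic
    inspiratory-shape corpus."""
    from .synth import generate_ifl_corpus

    X, y = generate_ifl_corpus(seed=seed)
    return ev.train_ifl_model(X, y, seed=seed)


@dataclass
class TraceAnalysis:
    """Cycles and events of one airflow trace."""

    flow: np.ndarray
    fs: float
    t0: float = 0.0
    cycles: list[br.BreathCycle] = field(default_factory=list)
    events: list[SDBEvent] = field(default_factory=list)


@dataclass
class RecordAnalysis(TraceAnalysis):
    stable: StablePeriods | None = None

    @property
    def stable_hours(self) -> float:
        return self.stable.total_s / 3600.0 if self.stable else 0.0


def _envelope_excursion(sig: np.ndarray, fs: float) -> np.ndarray:
    """Peak-to-valley excursion of an auxiliary channel (RIP bands, RIP flow,
    thermistance) via envelopes through its extrema; zero when the channel is
    too flat to carry extrema."""
    dist = max(int(1.0 * fs), 1)
    prom = 0.02 * max(float(np.ptp(sig)), 1e-12)
    peaks, _ = find_peaks(sig, distance=dist, prominence=prom)
    valleys, _ = find_peaks(-sig, distance=dist, prominence=prom)
    if len(peaks) < 2 or len(valleys) < 2:
        return np.zeros_like(sig)
    try:
        return br.compute_excursion(sig, peaks, valleys, fs).excursion
    except Exception:
        return np.zeros_like(sig)


def _detect_cycles(
    flow: np.ndarray, fs: float, config: PipelineConfig,
    rip_thorax: np.ndarray | None, rip_abdomen: np.ndarray | None,
    t0: float,
) -> tuple[list[br.BreathCycle], br.ExcursionTrack | None,
           list[br.ReducedSegment]]:
    peaks, valleys = br.detect_peaks_valleys(
        flow, fs, window_s=config.ampd_window_s, hop_s=config.ampd_hop_s,
        max_scale_s=config.ampd_max_scale_s, dedupe_s=config.dedupe_s)
    if len(peaks) < 2 or len(valleys) < 2:
        return [], None, []
    mean_ttot = float(np.median(np.diff(peaks))) / fs
    mean_amp = float(np.median(flow[peaks]) - np.median(flow[valleys]))
    peaks, valleys = br.rescue_missed_cycles(
        flow, peaks, valleys, fs, mean_amplitude=mean_amp,
        mean_ttot_s=mean_ttot, amp_fraction=config.rescue_amp_fraction,
        gap_factor=config.rescue_gap_factor)
    exc = br.compute_excursion(flow, peaks, valleys, fs)
    reduced = br.find_reduced_excursion_segments(
        exc, fraction=config.reduced_excursion_fraction,
        min_duration_s=config.reduced_min_duration_s,
        baseline_window_s=config.baseline_window_s)
    zeros = np.zeros_like(flow)
    cycles = br.detect_breath_onsets(
        flow, exc,
        rip_thorax if rip_thorax is not None else zeros,
        rip_abdomen if rip_abdomen is not None else zeros,
        reduced, fs, t0=t0, dedupe_s=config.dedupe_s)
    return cycles, exc, reduced


def _score_segment(
    flow: np.ndarray,
    exc: br.ExcursionTrack,
    cycles: list[br.BreathCycle],
    series: dict[str, np.ndarray],
    config: PipelineConfig,
    ifl_model: IFLModel | None,
    t0: float,
) -> list[SDBEvent]:
    fs = config.fs
    confirm_raw = series.get("thermistance", series.get("rip_flow"))
    confirm_exc = (_envelope_excursion(confirm_raw, fs)
                   if confirm_raw is not None else None)

    apneas = ev.detect_apneas(
        exc, confirm_exc,
        excursion_fraction=config.apnea_excursion_fraction,
        min_duration_s=config.min_event_duration_s,
        max_duration_s=config.max_event_duration_s,
        baseline_window_s=config.baseline_window_s,
        confirm_window_s=config.confirm_window_s,
        confirm_drop=config.apnea_confirm_drop, t0=t0)

    rip_t = series.get("rip_thorax")
    rip_a = series.get("rip_abdomen")
    exc_t = _envelope_excursion(rip_t, fs) if rip_t is not None else None
    exc_a = _envelope_excursion(rip_a, fs) if rip_a is not None else None
    for event in apneas:
        s = int((event.onset_s - t0) * fs)
        e = int((event.end_s - t0) * fs)
        if rip_t is None or rip_a is None:
            event.kind = br.CycleLabel.CA
            continue
        seg = br.ReducedSegment(max(0, s), min(len(flow), e), event.baseline_excursion)
        ref, detectable = br.select_reference_rip(rip_t, rip_a, seg, fs)
        if not detectable:
            event.kind = br.CycleLabel.CA
            event.attempts = []
            continue
        rip = rip_t if ref is br.OnsetSource.RIP_THORAX else rip_a
        rexc = exc_t if ref is br.OnsetSource.RIP_THORAX else exc_a
        ev.classify_apnea(
            event, rip, rexc, fs, significance=config.attempt_significance,
            confirm_window_s=config.confirm_window_s, t0=t0)

    hypopneas = ev.detect_hypopneas(
        exc, confirm_exc, apneas,
        excursion_fraction=config.hypopnea_excursion_fraction,
        min_duration_s=config.min_event_duration_s,
        max_duration_s=config.max_event_duration_s,
        baseline_window_s=config.baseline_window_s,
        confirm_window_s=config.confirm_window_s,
        confirm_drop=config.hypopnea_confirm_drop, t0=t0)

    audio = series.get("audio")
    for event in hypopneas:
        evidence: list[set[str]] = []
        inside = [c for c in cycles if event.onset_s <= c.onset_s < event.end_s]
        for c in inside:
            flags: set[str] = set()
            if audio is not None and ev.detect_snore(
                    audio, flow, c, fs, power_ratio=config.snore_power_ratio, t0=t0):
                flags.add("snore")
            if rip_t is not None and rip_a is not None and ev.detect_paradox(
                    rip_t, rip_a, c, fs, t0=t0):
                flags.add("paradox")
            if config.ifl_enabled and ifl_model is not None:
                i, k, _ = ev._insp_slice(flow, c, fs, t0)
                feats = ev.extract_ifl_features(
                    flow[i:k], event.baseline_excursion / 2.0)
                if ev.classify_ifl(feats, ifl_model):
                    flags.add("ifl")
            evidence.append(flags)
        ev.classify_hypopnea(event, evidence)

    return sorted(apneas + hypopneas, key=lambda e: e.onset_s)


def analyze_record(
    record: PolygraphRecord,
    config: PipelineConfig | None = None,
    ifl_model: IFLModel | None = None,
) -> RecordAnalysis:
    """Steps 2-5 on a preprocessed record, one stable period at a time."""
    config = config or PipelineConfig()
    fs = config.fs
    if record.vsource is None:
        raise ValueError("preprocess the record first")
    if ifl_model is None and config.ifl_enabled:
        ifl_model = get_ifl_model(config.ifl_seed)

    fe = frame_energy(record.series["accel_norm"], fs,
                      config.frame_len_samples, config.frame_hop_samples)
    threshold = adaptive_energy_threshold(
        fe, n_resample=config.energy_resample_n,
        slope_window=config.slope_window, slope_hop=config.slope_hop,
        slope_ratio=config.slope_ratio,
        min_sleep_fraction=config.min_sleep_fraction)
    stable = segment_stable_periods(fe, threshold,
                                    max_gap_s=config.max_movement_gap_s)

    out = RecordAnalysis(flow=record.vsource, fs=fs, stable=stable)
    for start_s, end_s in stable.intervals:
        i0, i1 = int(start_s * fs), min(int(end_s * fs), record.n_samples)
        if (i1 - i0) / fs < 60.0:
            log.info("stable period %.0f-%.0f s too short to analyze", start_s, end_s)
            continue
        series = {k: v[i0:i1] for k, v in record.series.items()}
        flow = record.vsource[i0:i1]
        cycles, exc, _ = _detect_cycles(
            flow, fs, config, series.get("rip_thorax"),
            series.get("rip_abdomen"), t0=start_s)
        if exc is None:
            continue
        events = _score_segment(flow, exc, cycles, series, config,
                                ifl_model, t0=start_s)
        ev.label_cycles(cycles, events)
        out.cycles.extend(cycles)
        out.events.extend(events)
    return out


def analyze_flow_trace(
    flow: np.ndarray,
    fs: float,
    config: PipelineConfig | None = None,
    t0: float = 0.0,
) -> TraceAnalysis:
    """Flow-only analysis (bench pneumotachograph trace): breath cycles and
    unconfirmed apnea candidates, no effort-based classification."""
    config = config or PipelineConfig()
    flow = np.asarray(flow, dtype=float)
    cycles, exc, _ = _detect_cycles(flow, fs, config, None, None, t0)
    events: list[SDBEvent] = []
    if exc is not None:
        events = ev.detect_apneas(
            exc, None, allow_unconfirmed=True,
            excursion_fraction=config.apnea_excursion_fraction,
            min_duration_s=config.min_event_duration_s,
            max_duration_s=config.max_event_duration_s,
            baseline_window_s=config.baseline_window_s, t0=t0)
    return TraceAnalysis(flow=flow, fs=fs, t0=t0, cycles=cycles, events=events)


# ---------------------------------------------------------------------------
# commands + replay


@dataclass
class PipelineResult:
    analysis: RecordAnalysis
    commands: BenchCommandSet
    calibration: StarlingCalibration
    lung: LungModel
    starling: StarlingModel


def build_bench_commands(
    record: PolygraphRecord,
    analysis: RecordAnalysis,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Step 6 over the whole night.  V'cc is zeroed outside stable periods:
    nothing there is replayed or evaluated."""
    config = config or PipelineConfig()
    lung = LungModel(config.lung_compliance_ml, config.lung_resistance, config.fs)
    starling = StarlingModel(config.starling_pus, config.starling_rus,
                             pch_max=config.starling_pch_max)
    calibration = calibrate_starling(starling, config.fs)
    commands = build_commands(
        record.vsource, analysis.cycles, analysis.events, lung, calibration,
        fs=config.fs)
    if analysis.stable is not None:
        mask = np.zeros(len(commands.vcc), dtype=bool)
        for s, e in analysis.stable.intervals:
            mask[int(s * config.fs):int(e * config.fs)] = True
        commands.vcc[~mask] = 0.0
        commands.pmus[~mask] = 0.0
    return PipelineResult(analysis, commands, calibration, lung, starling)


def replay(result: PipelineResult, config: PipelineConfig | None = None
           ) -> BenchTrace:
    config = config or PipelineConfig()
    return run_bench(
        result.commands, result.lung, result.starling,
        regulator_tau_s=config.regulator_tau_s,
        transition_artifact=config.transition_artifact)


def compare_traces(
    source: TraceAnalysis,
    bench: TraceAnalysis,
    config: PipelineConfig | None = None,
) -> EvaluationReport:
    """Full agreement report between two analyzed traces.

    Amplitude/Ttot and morphology statistics cover the non-apneic matched
    cycles (apneas are compared at the event level instead, as sensitivity,
    PPV, onset and duration agreement).
    """
    config = config or PipelineConfig()
    pairs = match_cycles(source.cycles, bench.cycles, config.match_tolerance_s)
    apnea_kinds = (br.CycleLabel.OA, br.CycleLabel.CA)
    keep = [(i, j) for i, j in pairs
            if source.cycles[i].label not in apnea_kinds]
    report = EvaluationReport()
    if len(keep) >= 2:
        report = amplitude_ttot_agreement(
            source.cycles, bench.cycles, keep, report,
            baseline_window_s=config.baseline_window_s)
        report = morphology_correlation(
            source.cycles, bench.cycles, keep, source.flow, bench.flow,
            config.fs, t0_source=source.t0, t0_bench=bench.t0,
            min_samples=config.min_cycle_samples, report=report)
    report = apnea_agreement(
        source.events, bench.events,
        overlap_fraction=config.apnea_overlap_fraction, report=report)
    return report


# ---------------------------------------------------------------------------
# exports


def cycles_to_csv(cycles: list[br.BreathCycle], path: str | Path) -> None:
    import pandas as pd
    pd.DataFrame([{
        "onset_s": c.onset_s, "ttot_s": c.ttot_s, "amplitude": c.amplitude,
        "onset_source": c.onset_source.value, "label": c.label.value,
    } for c in cycles]).to_csv(path, index=False, float_format="%.6f")


def events_to_csv(events: list[SDBEvent], path: str | Path) -> None:
    import pandas as pd
    pd.DataFrame([{
        "onset_s": e.onset_s, "duration_s": e.duration_s,
        "kind": e.kind.value if e.kind else "unclassified",
        "evidence": "|".join(sorted(e.evidence)),
        "n_attempts": len(e.attempts),
        "n_significant": sum(1 for _, s in e.attempts if s),
        "baseline_excursion": e.baseline_excursion,
        "confirmed": e.confirmed,
    } for e in events]).to_csv(path, index=False, float_format="%.6f")


def events_to_json(events: list[SDBEvent], stable_hours: float,
                   path: str | Path) -> None:
    import json
    payload = {
        "events": [{
            "onset_s": round(e.onset_s, 3), "duration_s": round(e.duration_s, 3),
            "kind": e.kind.value if e.kind else "unclassified",
            "evidence": sorted(e.evidence),
        } for e in events],
        "indices": ev.event_indices(events, stable_hours) if stable_hours > 0 else {},
    }
    Path(path).write_text(json.dumps(payload, indent=1))
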