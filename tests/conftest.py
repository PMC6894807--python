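"""Shared fixtures: synthetic recordings at two scales and the full
closed-loop replay bundle, built once per session."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pytest

from respibench import pipeline as pl
from respibench.breaths import CycleLabel
from respibench.config import PipelineConfig
from respibench.events import SDBEvent
from respibench.io_polygraph import preprocess
from respibench.synth import (
    GroundTruth, SyntheticScenario, default_night_scenario, generate_polygraph,
)

logging.getLogger("respibench").setLevel(logging.ERROR)

KIND_MAP = {
    "OA": CycleLabel.OA, "CA": CycleLabel.CA,
    "OH": CycleLabel.OH, "CH": CycleLabel.CH,
}


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def short_record(config):
    """A ten-minute event-free night, preprocessed, with its ground truth."""
    record, gt = generate_polygraph(SyntheticScenario(duration_s=600.0, seed=1))
    return preprocess(record, config), gt


@dataclass
class NightBundle:
    record: object
    gt: GroundTruth
    analysis: pl.RecordAnalysis
    result: pl.PipelineResult
    trace: object
    bench: pl.TraceAnalysis
    report: object


@pytest.fixture(scope="session")
def night(config) -> NightBundle:
    """The full study night (just over two hours, 48 scripted events of all
    four kinds) pushed through analysis, command synthesis, the virtual
    bench, and the agreement evaluation."""
    record, gt = generate_polygraph(default_night_scenario(seed=1))
    record = preprocess(record, config)
    analysis = pl.analyze_record(record, config)
    result = pl.build_bench_commands(record, analysis, config)
    trace = pl.replay(result, config)
    bench = pl.analyze_flow_trace(trace.vbench, config.fs, config, t0=trace.t[0])
    source = pl.TraceAnalysis(flow=record.vsource, fs=config.fs,
                              cycles=analysis.cycles, events=analysis.events)
    report = pl.compare_traces(source, bench, config)
    return NightBundle(record, gt, analysis, result, trace, bench, report)


def match_gt_events(
    gt: GroundTruth, detected: list[SDBEvent], overlap_fraction: float = 0.5,
) -> list[tuple[dict, SDBEvent]]:
    """Greedy overlap matching of scripted events to detections."""
    used: set[int] = set()
    pairs: list[tuple[dict, SDBEvent]] = []
    for g in gt.events:
        g0, g1 = g["onset_s"], g["onset_s"] + g["duration_s"]
        best, best_ov = None, 0.0
        for k, e in enumerate(detected):
            if k in used:
                continue
            ov = min(g1, e.end_s) - max(g0, e.onset_s)
            if ov >= overlap_fraction * min(g1 - g0, e.duration_s) and ov > best_ov:
                best, best_ov = k, ov
        if best is not None:
            used.add(best)
            pairs.append((g, detected[best]))
    return pairs
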