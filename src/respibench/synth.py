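"""Ground-truthed synthetic polygraph nights.

Real overnight recordings are large and proprietary, so every pipeline stage
is exercised against scripted nights generated here: breath-by-breath nasal
airflow with cycle-to-cycle variability, squared into a nasal-pressure
channel (the inverse of the square-root estimate), respiratory-inductance
bands in phase with the airflow (anti-phase during scripted paradox,
persisting during obstructive apneas, suppressed during central ones), audio
with inspiratory bursts during scripted snoring, an accelerometer noise
floor with high-energy movement bursts, and a ground-truth annotation track
listing every cycle onset and scripted event.

The generator writes standard EDF at the native channel rates of a typical
polygraph (nasal pressure 200 Hz, RIP 25 Hz, audio 100 Hz, accelerometer
20 Hz, SpO2 3 Hz) so the reader is tested end-to-end.

Default conditions: Ttot 4.0 +/- 0.3 s, inspiratory peak flow 0.5 L/s with
10% log-normal jitter, apneas retaining 5% of the airflow and hypopneas 50%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .breaths import CycleLabel
from .config import DEFAULT_CHANNEL_MAP
from .edf import write_edf
from .io_polygraph import Channel, PolygraphRecord

MASTER_RATE = 200.0
NATIVE_RATES = {
    "nasal_pressure": 200.0, "rip_thorax": 25.0, "rip_abdomen": 25.0,
    "rip_flow": 25.0, "audio": 100.0, "accel_norm": 20.0, "spo2": 3.0,
}

EVENT_KINDS = ("OA", "CA", "OH", "CH", "movement")
_KIND_TO_LABEL = {
    "OA": CycleLabel.OA, "CA": CycleLabel.CA,
    "OH": CycleLabel.OH, "CH": CycleLabel.CH,
}

# per-label multipliers: airflow, effort (RIP bands), RIP-flow channel
_FLOW_FACTOR = {CycleLabel.NORMAL: 1.0, CycleLabel.OA: 0.05,
                CycleLabel.CA: 0.05, CycleLabel.OH: 0.5, CycleLabel.CH: 0.5}
_EFFORT_FACTOR = {CycleLabel.NORMAL: 1.0, CycleLabel.OA: 0.8,
                  CycleLabel.CA: 0.05, CycleLabel.OH: 0.9, CycleLabel.CH: 0.6}
_RIPFLOW_FACTOR = {CycleLabel.NORMAL: 1.0, CycleLabel.OA: 0.5,
                   CycleLabel.CA: 0.1, CycleLabel.OH: 0.75, CycleLabel.CH: 0.7}


@dataclass
class ScriptedEvent:
    kind: str
    onset_s: float
    duration_s: float
    depth: float = 0.5

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class SyntheticScenario:
    duration_s: float = 600.0
    base_ttot_s: float = 4.0
    ttot_sd_s: float = 0.3
    base_amplitude: float = 0.5          # inspiratory peak flow, L/s
    amplitude_jitter_sd: float = 0.10    # log-normal sigma
    event_script: list[ScriptedEvent] = field(default_factory=list)
    snore_on_obstruction: bool = True
    paradox_on_obstruction: bool = True
    flatten_obstructed: bool = True
    noise: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        evs = sorted(self.event_script, key=lambda e: e.onset_s)
        for a, b in zip(evs[:-1], evs[1:]):
            if b.onset_s < a.end_s:
                raise ValueError(
                    f"scripted events overlap at {a.onset_s}/{b.onset_s} s")
        for e in evs:
            if e.kind not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {e.kind!r}")
            if not 0.0 <= e.depth <= 1.0:
                raise ValueError("event depth must be in [0, 1]")


@dataclass
class GroundTruth:
    """Scripted annotations: every cycle onset and every realized event."""

    cycles: list[dict] = field(default_factory=list)   # onset_s, ttot_s, label
    events: list[dict] = field(default_factory=list)   # kind, onset_s, duration_s
    movement: list[dict] = field(default_factory=list)

    def cycle_onsets(self) -> np.ndarray:
        return np.array([c["onset_s"] for c in self.cycles])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"cycles": self.cycles, "events": self.events,
             "movement": self.movement}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(d["cycles"], d["events"], d.get("movement", []))


def _breath_template(
    amp: float, ttot_s: float, rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(flow, volume) over one cycle: half-sine inspiration (Ti/Ttot = 0.4),
    exponential-decay expiration scaled so the cycle volume is zero."""
    n = max(int(round(ttot_s * rate)), 4)
    ni = max(int(round(0.4 * n)), 2)
    ne = n - ni
    insp = amp * np.sin(np.pi * np.arange(ni) / ni)
    tau = ne / 1.5
    shape = np.exp(-np.arange(ne) / tau) - np.exp(-ne / tau)
    b = insp.sum() / max(shape.sum(), 1e-12)
    flow = np.concatenate([insp, -b * shape])
    volume = np.cumsum(flow) / rate
    return flow, volume


def generate_polygraph(
    scenario: SyntheticScenario,
) -> tuple[PolygraphRecord, GroundTruth]:
    """Synthesize all channels of one night plus its annotation track.

    Deterministic given the scenario (including its seed): identical inputs
    produce bit-identical channels.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    rate = MASTER_RATE
    n_total = int(round(scenario.duration_s * rate))
    gt = GroundTruth()

    flow = np.zeros(n_total)
    rip_vol = np.zeros(n_total)      # unit-amplitude volume shape per cycle
    effort = np.ones(n_total)        # per-cycle effort multiplier
    paradox_mask = np.zeros(n_total, dtype=bool)
    snore_mask = np.zeros(n_total, dtype=bool)   # inspiratory samples only
    ripflow = np.zeros(n_total)

    events = sorted((e for e in scenario.event_script if e.kind != "movement"),
                    key=lambda e: e.onset_s)
    realized: dict[int, list[tuple[float, float]]] = {}

    t = 0.0
    while t < scenario.duration_s and n_total > 0:
        ttot = float(np.clip(
            rng.normal(scenario.base_ttot_s, scenario.ttot_sd_s),
            max(1.5, scenario.base_ttot_s - 3 * scenario.ttot_sd_s),
            scenario.base_ttot_s + 3 * scenario.ttot_sd_s))
        amp = scenario.base_amplitude * float(
            rng.lognormal(0.0, scenario.amplitude_jitter_sd))
        label = CycleLabel.NORMAL
        ev_idx = None
        for k, e in enumerate(events):
            if e.onset_s <= t < e.end_s:
                label = _KIND_TO_LABEL[e.kind]
                ev_idx = k
                break

        cyc_flow, cyc_vol = _breath_template(amp, ttot, rate)
        i0 = int(round(t * rate))
        sl = slice(i0, min(i0 + len(cyc_flow), n_total))
        m = sl.stop - sl.start
        if m <= 0:
            break

        f = cyc_flow.copy()
        depth_residual = _FLOW_FACTOR[label]
        if ev_idx is not None and label in (CycleLabel.OH, CycleLabel.CH):
            depth_residual = 1.0 - events[ev_idx].depth
        f *= depth_residual
        if (scenario.flatten_obstructed and label is CycleLabel.OH
                and np.max(f) > 0):
            # plateau-clip the inspiratory limb to exercise the IFL detector
            f = np.where(f > 0, np.minimum(f, 0.7 * np.max(f)), f)

        flow[sl] = f[:m]
        vmax = max(float(np.max(cyc_vol)), 1e-12)
        rip_vol[sl] = cyc_vol[:m] / vmax
        effort[sl] = _EFFORT_FACTOR[label]
        ripflow[sl] = (0.8 * cyc_flow[:m]) * _RIPFLOW_FACTOR[label]
        if label.name in ("OA", "OH"):
            if scenario.paradox_on_obstruction:
                paradox_mask[sl] = True
            if scenario.snore_on_obstruction:
                insp = cyc_flow[:m] > 0
                snore_mask[sl] = insp
        gt.cycles.append({"onset_s": round(t, 4), "ttot_s": round(ttot, 4),
                          "label": label.value})
        if ev_idx is not None:
            realized.setdefault(ev_idx, []).append((t, t + ttot))
        t += ttot

    for k, spans in sorted(realized.items()):
        onset = spans[0][0]
        end = min(spans[-1][1], scenario.duration_s)
        gt.events.append({"kind": events[k].kind, "onset_s": round(onset, 4),
                          "duration_s": round(end - onset, 4)})

    # --- channels at native rates -----------------------------------------
    noise = scenario.noise
    nasal = np.sign(flow) * flow ** 2
    nasal += rng.normal(0.0, noise * scenario.base_amplitude ** 2,
                        n_total)

    thorax = 0.6 * rip_vol * effort
    abdomen = 0.6 * rip_vol * effort
    abdomen[paradox_mask] *= -1.0
    thorax += rng.normal(0.0, 0.01, n_total)
    abdomen += rng.normal(0.0, 0.01, n_total)
    ripflow = ripflow + rng.normal(0.0, noise * scenario.base_amplitude, n_total)

    audio = 0.1 + 0.05 * np.abs(rng.normal(0.0, 1.0, n_total))
    audio[snore_mask] += 1.0

    n20 = int(round(scenario.duration_s * 20.0))
    accel = np.abs(1.0 + rng.normal(0.0, 0.02, n20))
    for e in scenario.event_script:
        if e.kind != "movement":
            continue
        i0, i1 = int(e.onset_s * 20), min(int(e.end_s * 20), n20)
        accel[i0:i1] += np.abs(rng.normal(0.0, 2.0, max(i1 - i0, 0)))
        gt.movement.append({"onset_s": e.onset_s, "duration_s": e.duration_s})

    n3 = int(round(scenario.duration_s * 3.0))
    spo2 = 96.0 + rng.normal(0.0, 0.2, n3)

    def dec(x: np.ndarray, target: float) -> np.ndarray:
        step = int(round(MASTER_RATE / target))
        return x[::step].copy()

    channels = {
        "nasal_pressure": Channel(nasal, 200.0),
        "rip_thorax": Channel(dec(thorax, 25.0), 25.0),
        "rip_abdomen": Channel(dec(abdomen, 25.0), 25.0),
        "rip_flow": Channel(dec(ripflow, 25.0), 25.0),
        "audio": Channel(dec(audio, 100.0), 100.0),
        "accel_norm": Channel(accel, 20.0),
        "spo2": Channel(spo2, 3.0),
    }
    record = PolygraphRecord(channels=channels,
                             channel_map=dict(DEFAULT_CHANNEL_MAP))
    return record, gt


def write_scenario_edf(
    record: PolygraphRecord, path: str | Path,
    channel_map: dict[str, str] | None = None,
) -> None:
    """Write a generated record as standard EDF under the default (Nox-style)
    channel names."""
    channel_map = channel_map or DEFAULT_CHANNEL_MAP
    signals = [(channel_map[role], ch.rate, ch.data)
               for role, ch in record.channels.items() if role in channel_map]
    write_edf(path, signals)


# ---------------------------------------------------------------------------
# canned scenarios


def default_night_scenario(
    duration_s: float = 7680.0,
    seed: int = 0,
    *,
    n_events_per_kind: int = 12,
    event_duration_s: tuple[float, float] = (15.0, 25.0),
    first_event_s: float = 300.0,
    spacing_s: float = 150.0,
    hypopnea_depth: float = 0.5,
    movement: bool = True,
) -> SyntheticScenario:
    """A study night: a little over two hours with all four event kinds
    interleaved at regular spacing (about 22.5 events/h, a moderate-severity
    profile) plus a couple of movement bursts."""
    rng = np.random.default_rng(seed + 1)
    script: list[ScriptedEvent] = []
    kinds = ("OA", "CA", "OH", "CH") * n_events_per_kind
    t = first_event_s
    for kind in kinds:
        if t + event_duration_s[1] > duration_s - 60.0:
            break
        dur = float(rng.uniform(*event_duration_s))
        script.append(ScriptedEvent(kind, round(t, 1), round(dur, 1),
                                    depth=hypopnea_depth))
        t += spacing_s
    if movement:
        for onset in (first_event_s / 2, duration_s - 120.0):
            script.append(ScriptedEvent("movement", round(onset, 1), 20.0))
    return SyntheticScenario(
        duration_s=duration_s, event_script=script, seed=seed)


def generate_ifl_corpus(
    n_per_class: int = 600, seed: int = 42,
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled inspiratory-shape corpus for the flow-limitation network.

    Class 0: rounded (half-sine) inspirations; class 1: flow-limited
    (plateau-clipped) inspirations.  Limbs reach the feature extractor the
    way the pipeline sees them: a full breath cycle is squared into a nasal
    pressure signal, degraded with sensor noise, Savitzky-Golay smoothed,
    square-rooted back to flow, and the positive limb is cut at its zero
    crossings — so training and inference share shaping, scaling and
    sampling.
    """
    from .events import extract_ifl_features
    from .io_polygraph import nasal_pressure_to_flow, savgol_smooth

    rng = np.random.default_rng(seed)
    base_amp = 0.5                   # unreduced inspiratory peak, L/s
    rows, labels = [], []
    for label in (0, 1):
        for _ in range(n_per_class):
            ttot = float(rng.uniform(2.5, 6.0))
            amp = base_amp * float(rng.uniform(0.3, 0.8))  # hypopnea range
            flow, _ = _breath_template(amp, ttot, 20.0)
            if label == 1:
                flow = np.where(
                    flow > 0,
                    np.minimum(flow, float(rng.uniform(0.55, 0.8)) * amp),
                    flow)
            # embed between neighbouring expirations so smoothing sees the
            # same context as in a night recording
            pre, _ = _breath_template(amp, ttot, 20.0)
            sig = np.concatenate([pre[int(0.4 * len(pre)):], flow])
            pressure = np.sign(sig) * sig ** 2
            pressure += rng.normal(0.0, 0.01 * base_amp ** 2, len(pressure))
            v = nasal_pressure_to_flow(savgol_smooth(pressure, 20.0))
            k = len(pre) - int(0.4 * len(pre))
            while k < len(v) and v[k] <= 0:
                k += 1
            j = k
            while j < len(v) and v[j] > 0:
                j += 1
            limb = v[k:j]
            # the normalized amplitude must not leak the class: rounded
            # hypopnea limbs are small too, so both classes see the full
            # plausible range of peak/baseline ratios
            baseline = amp / float(rng.uniform(0.3, 1.2))
            f = extract_ifl_features(limb, baseline_amp=baseline)
            if f.degenerate:
                continue
            rows.append(f.as_array())
            labels.append(label)
    return np.array(rows), np.array(labels)
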