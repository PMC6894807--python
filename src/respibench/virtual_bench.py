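"""Software surrogate of the bench hardware.

The physical bench — an active lung simulator driven by dP_mus, a Starling
resistor whose chamber pressure is stepped at each cycle trigger, and a 20 Hz
acquisition chain — is replaced by:

* :func:`simulate_lung` — solves ``R*V' + V/C = -dP_mus`` for the flow with
  an implicit trapezoidal step that exactly inverts the trapezoidal volume
  integral used when the commands were computed (per-cycle volume reset
  included), so replaying a command set reproduces its V'cc to round-off;
* :func:`simulate_starling` — a first-order chamber-pressure regulator
  followed by a memoryless waterfall clip of the instantaneous flow at the
  admissible peak flow for the effective chamber pressure.

A constant-pressure controller stub (:class:`ConstantPressureController`) is
provided for closed-loop demonstrations; no APAP algorithm is implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .commands import BenchCommandSet, LungModel, StarlingModel
from .errors import DataQualityError


@dataclass
class BenchTrace:
    """Simulated bench output on the 20 Hz grid."""

    t: np.ndarray                  # seconds
    vbench: np.ndarray             # L/s
    pch_applied: np.ndarray        # cmH2O, after regulator dynamics
    pus_applied: float = 4.0

    @property
    def fs(self) -> float:
        return 1.0 / (self.t[1] - self.t[0]) if len(self.t) > 1 else 20.0

    def write_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "t_s": self.t, "vbench": self.vbench, "pch_applied": self.pch_applied,
        }).to_csv(path, index=False, float_format="%.6f")


def simulate_lung(
    pmus: np.ndarray,
    lung: LungModel,
    trigger_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Flow of the single-compartment lung under a dP_mus command.

    Solves ``R*V' + V/C = -dP_mus`` with the implicit trapezoidal scheme
    (A-stable at 20 Hz for the default time constant R*C = 0.58 s), with the
    volume reset to zero at each cycle trigger exactly as the command
    generator assumes.
    """
    p = np.asarray(pmus, dtype=float)
    if not np.all(np.isfinite(p)):
        raise DataQualityError("non-finite dP_mus command")
    dt = 1.0 / lung.fs
    C = lung.compliance_l
    R = lung.resistance
    if trigger_indices is None or len(trigger_indices) == 0:
        starts = {0}
    else:
        starts = set(int(i) for i in trigger_indices)
        starts.add(0)
    flow = np.zeros_like(p)
    vol = 0.0
    prev_flow = 0.0
    for n in range(len(p)):
        if n in starts:
            vol = 0.0
            flow[n] = -p[n] / R if R > 0 else 0.0
        else:
            vol_half = vol + dt / 2.0 * prev_flow
            flow[n] = (-p[n] - vol_half / C) / (R + dt / (2.0 * C))
            vol = vol_half + dt / 2.0 * flow[n]
        prev_flow = flow[n]
    return flow


def _regulator(pch_target: np.ndarray, tau_s: float, fs: float) -> np.ndarray:
    """First-order lag of the chamber-pressure control system."""
    if tau_s <= 0:
        return pch_target.astype(float)
    dt = 1.0 / fs
    alpha = dt / (tau_s + dt)       # implicit first-order step
    out = np.empty_like(pch_target, dtype=float)
    state = pch_target[0] if len(pch_target) else 0.0
    for n, target in enumerate(pch_target):
        state = state + alpha * (target - state)
        out[n] = state
    return out


def simulate_starling(
    flow_in: np.ndarray,
    pch: np.ndarray,
    model: StarlingModel,
    *,
    regulator_tau_s: float = 0.3,
    fs: float = 20.0,
    transition_artifact: bool = False,
) -> BenchTrace:
    """Pass a flow through the collapsible-tube surrogate.

    ``pch`` is the commanded chamber pressure per sample (piecewise constant
    per cycle in normal use); it is low-pass filtered by the regulator and
    the instantaneous flow is clipped to the waterfall admissible flow of the
    effective pressure.  Optionally a brief flow spike proportional to the
    commanded pressure step is injected at each obstruction onset, mimicking
    the physical tube's prompt collapse.
    """
    flow_in = np.asarray(flow_in, dtype=float)
    pch = np.asarray(pch, dtype=float)
    if len(pch) != len(flow_in):
        raise ValueError("pch series must match the flow length")
    eff = _regulator(pch, regulator_tau_s, fs)
    fmax = np.asarray(model.fmax(eff), dtype=float)
    out = np.clip(flow_in, -fmax, fmax)
    if transition_artifact:
        steps = np.flatnonzero(np.diff(pch) > 0) + 1
        for i in steps:
            out[i] += 0.05 * (pch[i] - pch[i - 1])
    t = np.arange(len(flow_in)) / fs
    return BenchTrace(t=t, vbench=out, pch_applied=eff, pus_applied=model.pus)


def run_bench(
    commands: BenchCommandSet,
    lung: LungModel,
    model: StarlingModel,
    *,
    regulator_tau_s: float = 0.3,
    transition_artifact: bool = False,
) -> BenchTrace:
    """Replay a command set: active lung, then Starling resistor.

    The chamber-pressure command is stepped at each cycle trigger (the TTL
    analogue) and held until the next; overlapping cycles are rejected.
    """
    n = len(commands.vcc)
    if n == 0:
        return BenchTrace(np.empty(0), np.empty(0), np.empty(0), model.pus)
    cycles = commands.cycles
    for a, b in zip(cycles[:-1], cycles[1:]):
        if b.trigger_s < a.end_s - 1e-9:
            raise ValueError(
                f"overlapping cycles at {a.trigger_s:.2f}/{b.trigger_s:.2f} s")
    pch = np.full(n, model.pch_min, dtype=float)
    idx = commands.trigger_indices
    for k, c in enumerate(cycles):
        a = idx[k]
        b = idx[k + 1] if k + 1 < len(cycles) else int(
            round((c.end_s - commands.t0) * commands.fs))
        pch[max(a, 0):min(b, n)] = c.pch
    flow = simulate_lung(commands.pmus, lung, idx)
    trace = simulate_starling(
        flow, pch, model, regulator_tau_s=regulator_tau_s, fs=commands.fs,
        transition_artifact=transition_artifact)
    trace.t = trace.t + commands.t0
    return trace


class ConstantPressureController:
    """Closed-loop stub: holds the upstream pressure constant.

    Stands in for an APAP device in closed-loop demonstrations; testing real
    APAP algorithms is out of scope.
    """

    def __init__(self, pressure_cmh2o: float = 4.0) -> None:
        self.pressure_cmh2o = pressure_cmh2o

    def update(self, _vbench_recent: np.ndarray) -> float:
        return self.pressure_cmh2o
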