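"""Bench command synthesis (step 6).

From the labelled breath cycles this module builds the two digital inputs of
the bench: the muscular-effort pressure waveform driving the active lung,

    dP_mus(t) = -V_cc(t)/C - R * V'cc(t),

with V_cc the running integral of the central-command airflow V'cc (reset at
each cycle trigger), and the per-cycle Starling chamber pressure P_ch that
attenuates the lung output down to the recorded airflow amplitude.

V'cc copies the recorded airflow for normal and central cycles; for
obstructive cycles — where the recorded airflow underestimates the central
command — it is reconstructed as a sinusoid at the pre-event baseline
amplitude, timed by the cycle boundaries (which come from the airflow for
obstructive hypopneas and from the reference RIP band for obstructive
apneas).

Units: flow L/s, volume L, pressure cmH2O; the lung compliance is converted
from mL/cmH2O at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .breaths import BreathCycle, CycleLabel
from .events import SDBEvent

log = logging.getLogger(__name__)


@dataclass
class LungModel:
    """Single-compartment lung: compliance C in series with resistance R."""

    compliance_ml: float = 80.0     # mL/cmH2O
    resistance: float = 7.25        # cmH2O/(L/s)
    fs: float = 20.0

    @property
    def compliance_l(self) -> float:
        return self.compliance_ml / 1000.0

    @property
    def time_constant_s(self) -> float:
        return self.resistance * self.compliance_l

    def __post_init__(self) -> None:
        if self.compliance_ml <= 0 or self.resistance < 0:
            raise ValueError("need C > 0 and R >= 0")


@dataclass
class StarlingModel:
    """Collapsible-tube surrogate with waterfall behavior.

    Flow is unrestricted while the chamber pressure is at its minimum;
    above the downstream pressure the admissible peak flow falls linearly,
    ``fmax = max(0, (pus - pch) / rus)``, reaching full occlusion at
    ``pch >= pus``.
    """

    pus: float = 4.0                # upstream pressure, cmH2O
    rus: float = 4.0                # upstream resistance, cmH2O/(L/s)
    pch_min: float = 0.0
    pch_max: float = 10.0

    def fmax(self, pch: np.ndarray | float) -> np.ndarray | float:
        """Admissible peak flow (L/s); infinite when the chamber is vented."""
        pch = np.asarray(pch, dtype=float)
        out = np.where(pch <= self.pch_min, np.inf,
                       np.maximum(0.0, (self.pus - pch) / self.rus))
        return out if out.ndim else float(out)


@dataclass
class CycleCommand:
    """Per-cycle record: the TTL-analogue trigger plus the chamber setting."""

    trigger_s: float
    end_s: float
    pch: float
    label: CycleLabel
    vcc_amplitude: float            # peak-to-valley of V'cc, L/s
    target_amplitude: float         # peak-to-valley of the recorded airflow


@dataclass
class BenchCommandSet:
    """Full-night command waveforms plus the per-cycle records."""

    fs: float
    t0: float
    vcc: np.ndarray                 # L/s on the 20 Hz grid
    pmus: np.ndarray                # cmH2O
    cycles: list[CycleCommand] = field(default_factory=list)

    @property
    def trigger_indices(self) -> np.ndarray:
        return np.array(
            [int(round((c.trigger_s - self.t0) * self.fs)) for c in self.cycles],
            dtype=int)

    def write_cycles_csv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame([{
            "trigger_s": c.trigger_s, "end_s": c.end_s, "pch": c.pch,
            "label": c.label.value, "vcc_amplitude": c.vcc_amplitude,
            "target_amplitude": c.target_amplitude,
        } for c in self.cycles]).to_csv(path, index=False, float_format="%.6f")

    def write_waveform_csv(self, path: str | Path) -> None:
        import pandas as pd
        t = self.t0 + np.arange(len(self.vcc)) / self.fs
        pd.DataFrame({"t_s": t, "pmus": self.pmus, "vcc": self.vcc}).to_csv(
            path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# V'cc estimation


def _cycle_slice(c: BreathCycle, fs: float, t0: float, n: int) -> slice:
    i = int(round((c.onset_s - t0) * fs))
    j = int(round((c.end_s - t0) * fs))
    return slice(max(0, i), min(n, j))


def estimate_vcc(
    flow: np.ndarray,
    cycles: list[BreathCycle],
    events: list[SDBEvent],
    fs: float = 20.0,
    t0: float = 0.0,
) -> np.ndarray:
    """Central-command airflow V'cc on the 20 Hz grid.

    Normal and central cycles copy the recorded airflow.  Obstructive cycles
    are reconstructed as one full sine over the cycle, with equal inspiratory
    and expiratory phases (volume-balanced by construction) and amplitude
    half the obstructive event's 2-minute pre-event baseline excursion.
    """
    flow = np.asarray(flow, dtype=float)
    vcc = flow.copy()
    mean_amp = (np.mean([c.amplitude for c in cycles]) if cycles else 0.0)
    for c in cycles:
        if not c.obstructive:
            continue
        event = next(
            (e for e in events
             if e.kind in (CycleLabel.OA, CycleLabel.OH)
             and e.onset_s <= c.onset_s < e.end_s), None)
        baseline = event.baseline_excursion if event is not None else 0.0
        if baseline <= 0:
            baseline = mean_amp
            log.info("no pre-event baseline for cycle at %.1f s; using "
                     "record mean amplitude", c.onset_s)
        amp = baseline / 2.0
        sl = _cycle_slice(c, fs, t0, len(flow))
        m = sl.stop - sl.start
        if m < 2:
            continue
        tau = np.arange(m) / m
        vcc[sl] = amp * np.sin(2.0 * np.pi * tau)
    return vcc


def equilibrate_volumes(
    cycle_vcc: np.ndarray, fs: float = 20.0, tol_l: float = 1e-6,
) -> np.ndarray:
    """Scale the lesser-volume phase of one cycle so inspired and expired
    volumes match (a bench-hardware requirement: the piston must return to
    its starting position each cycle).

    Phases are the positive- and negative-flow samples; scaling a phase by a
    constant leaves its extremum position unchanged.  Cycles with an absent
    phase (apneic copies) are returned unchanged.
    """
    v = np.asarray(cycle_vcc, dtype=float).copy()
    dt = 1.0 / fs
    pos = v > 0
    neg = v < 0
    vi = float(np.sum(v[pos])) * dt
    ve = float(-np.sum(v[neg])) * dt
    if vi <= tol_l or ve <= tol_l:
        if abs(vi - ve) > tol_l:
            log.debug("cycle with a single phase left unbalanced (%.2g vs %.2g L)",
                      vi, ve)
        return v
    if abs(vi - ve) <= tol_l:
        return v
    if vi > ve:
        v[neg] *= vi / ve
    else:
        v[pos] *= ve / vi
    return v


def compute_pmus(
    vcc: np.ndarray,
    lung: LungModel,
    trigger_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Muscular-effort pressure from V'cc.

    The lung volume is the trapezoidal running integral of V'cc, reset to
    zero at each cycle trigger so integration drift cannot accumulate across
    the night.
    """
    v = np.asarray(vcc, dtype=float)
    dt = 1.0 / lung.fs
    if trigger_indices is None or len(trigger_indices) == 0:
        starts = np.array([0], dtype=int)
    else:
        starts = np.unique(np.clip(trigger_indices, 0, max(len(v) - 1, 0)))
        if len(starts) == 0 or starts[0] != 0:
            starts = np.concatenate([[0], starts])
    vol = np.zeros_like(v)
    bounds = list(starts) + [len(v)]
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 1:
            continue
        seg = v[a:b]
        inc = np.zeros(b - a)
        inc[1:] = dt * (seg[:-1] + seg[1:]) / 2.0
        vol[a:b] = np.cumsum(inc)
    return -vol / lung.compliance_l - lung.resistance * v


# ---------------------------------------------------------------------------
# Starling calibration and P_ch


@dataclass
class StarlingCalibration:
    """Monotone attenuation tables measured on the virtual bench.

    For each phase the sweep yields the admissible peak flow as a function of
    chamber pressure; the inverse map (needed flow -> pch) is what
    :func:`compute_pch` uses.  The zero-flow plateau is collapsed onto the
    largest swept pressure so a full occlusion command saturates the
    regulator quickly.
    """

    pch_grid: np.ndarray
    fmax_insp: np.ndarray
    fmax_exp: np.ndarray
    model: StarlingModel

    def _inverse(self, fmax_tab: np.ndarray, f_needed: float) -> float:
        # table is non-increasing in pch; flip for np.interp
        pch = self.pch_grid[::-1]
        f = fmax_tab[::-1]
        # collapse the zero plateau: keep only the largest pch at f == 0
        nz = f > 0
        if nz.any():
            first = int(np.argmax(nz))
            keep = np.zeros(len(f), dtype=bool)
            keep[max(first - 1, 0):] = True
            pch, f = pch[keep], f[keep]
        f, idx = np.unique(f, return_index=True)
        pch = pch[idx]
        if f_needed >= f[-1]:
            return float(self.model.pch_min)
        return float(np.interp(f_needed, f, pch))

    def pch_for(self, target_amp: float, vcc_amp: float) -> float:
        """Chamber pressure turning a V'cc cycle of peak-to-valley amplitude
        ``vcc_amp`` into ``target_amp`` on the bench."""
        if vcc_amp <= 0:
            return float(self.model.pch_min)
        ratio = target_amp / vcc_amp
        if ratio > 1.0:
            log.warning("target amplitude exceeds V'cc amplitude (ratio %.2f); "
                        "tube left fully open", ratio)
            return float(self.model.pch_min)
        f_needed = ratio * vcc_amp / 2.0   # per-phase peak flow
        p_i = self._inverse(self.fmax_insp, f_needed)
        p_e = self._inverse(self.fmax_exp, f_needed)
        return float((p_i + p_e) / 2.0)


def calibrate_starling(
    model: StarlingModel,
    fs: float = 20.0,
    *,
    amplitudes: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0),
    n_grid: int = 41,
    period_s: float = 4.0,
) -> StarlingCalibration:
    """Sweep the chamber pressure on the virtual bench and measure, per
    phase, the output/input amplitude ratio of reference sinusoid flows.

    The measured attenuation must be non-increasing in pch; a non-monotone
    sweep indicates a misconfigured model and raises.
    """
    from .virtual_bench import simulate_starling  # late import: bench uses our types

    pch_grid = np.linspace(model.pch_min, model.pch_max, n_grid)
    t = np.arange(int(period_s * fs)) / fs
    fmax_i = np.full(n_grid, -np.inf)
    fmax_e = np.full(n_grid, -np.inf)
    for amp in amplitudes:
        ref = amp * np.sin(2 * np.pi * t / period_s)
        for k, pch in enumerate(pch_grid):
            trace = simulate_starling(
                ref, np.full(len(ref), pch), model, regulator_tau_s=0.0, fs=fs)
            out_i = float(np.max(trace.vbench))
            out_e = float(-np.min(trace.vbench))
            # a clipped phase reveals the admissible peak flow directly
            fmax_i[k] = max(fmax_i[k], out_i if out_i < amp * 0.999 else amp)
            fmax_e[k] = max(fmax_e[k], out_e if out_e < amp * 0.999 else amp)
    for name, tab in (("inspiratory", fmax_i), ("expiratory", fmax_e)):
        if np.any(np.diff(tab) > 1e-9):
            raise ValueError(f"non-monotone {name} attenuation sweep; "
                             "check the Starling model parameters")
    return StarlingCalibration(pch_grid, fmax_i, fmax_e, model)


def compute_pch(
    cycle: BreathCycle,
    vcc_amp: float,
    target_amp: float,
    calibration: StarlingCalibration,
) -> float:
    """Per-cycle chamber pressure.

    Obstructive cycles invert the calibrated attenuation law at the ratio
    ``target_amp / vcc_amp``; normal and central cycles leave the tube fully
    open (chamber at minimum).
    """
    if not cycle.obstructive:
        return float(calibration.model.pch_min)
    return calibration.pch_for(target_amp, vcc_amp)


# ---------------------------------------------------------------------------
# assembly


def build_commands(
    flow: np.ndarray,
    cycles: list[BreathCycle],
    events: list[SDBEvent],
    lung: LungModel,
    calibration: StarlingCalibration,
    fs: float = 20.0,
    t0: float = 0.0,
) -> BenchCommandSet:
    """Full step 6: V'cc, per-cycle volume equilibration, dP_mus and P_ch."""
    vcc = estimate_vcc(flow, cycles, events, fs, t0)
    n = len(vcc)
    for c in cycles:
        sl = _cycle_slice(c, fs, t0, n)
        vcc[sl] = equilibrate_volumes(vcc[sl], fs)

    records: list[CycleCommand] = []
    for c in cycles:
        sl = _cycle_slice(c, fs, t0, n)
        seg = vcc[sl]
        vamp = float(np.max(seg) - np.min(seg)) if len(seg) else 0.0
        pch = compute_pch(c, vamp, c.amplitude, calibration)
        records.append(CycleCommand(
            trigger_s=c.onset_s, end_s=c.end_s, pch=pch, label=c.label,
            vcc_amplitude=vamp, target_amplitude=c.amplitude))

    cmd = BenchCommandSet(fs=fs, t0=t0, vcc=vcc, pmus=np.zeros(n), cycles=records)
    cmd.pmus = compute_pmus(vcc, lung, cmd.trigger_indices)
    return cmd
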