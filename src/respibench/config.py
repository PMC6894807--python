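"""Pipeline configuration.

All tunable thresholds of the polygraph-to-bench pipeline live here, with the
published defaults.  The config serializes losslessly to/from YAML so a run can
be reproduced from its config file alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Default mapping from canonical channel role to recording channel name
#: (Nox T3-style labels).  Accelerometer may be a precomputed norm
#: ("accel_norm") or three axes ("accel_x/y/z").
DEFAULT_CHANNEL_MAP: dict[str, str] = {
    "accel_norm": "Activity",
    "nasal_pressure": "Nasal Pressure",
    "rip_thorax": "Thorax",
    "rip_abdomen": "Abdomen",
    "rip_flow": "RIP Flow",
    "audio": "Audio Volume",
    "spo2": "SpO2",
    "thermistance": "Thermistance",
}


@dataclass
class PipelineConfig:
    """Every threshold of the six processing steps plus the bench constants.

    Pressure unit is cmH2O, flow L/s, volume L, time seconds throughout.
    """

    # -- timebase -----------------------------------------------------------
    fs: float = 20.0                      # common analysis rate, Hz

    # -- step 1: preprocessing ---------------------------------------------
    savgol_window_s: float = 1.0          # Savitzky-Golay window length
    savgol_order: int = 3                 # polynomial order

    # -- step 2: stability segmentation ------------------------------------
    frame_len_samples: int = 100          # 5 s frames at 20 Hz
    frame_hop_samples: int = 50           # 50% overlap
    energy_resample_n: int = 1080         # sorted-energy array length
    slope_window: int = 6                 # points per regression window
    slope_hop: int = 3                    # 50% overlap between windows
    slope_ratio: float = 5.8              # change-point ratio (empirical)
    min_sleep_fraction: float = 0.25      # scan starts at 25% of the slopes
    max_movement_gap_s: float = 120.0     # movement gaps absorbed if shorter

    # -- step 3: breath detection ------------------------------------------
    ampd_window_s: float = 180.0          # AMPD moving-window length
    ampd_hop_s: float = 90.0              # half-window hop for stitching
    ampd_max_scale_s: float = 12.5        # largest AMPD scale considered
    dedupe_s: float = 0.25                # duplicate-extremum suppression
    rescue_amp_fraction: float = 0.2      # missed-cycle amplitude threshold
    rescue_gap_factor: float = 1.5        # gap > factor * recent mean Ttot
    reduced_excursion_fraction: float = 0.35  # <= 35% of baseline (65% drop)
    reduced_min_duration_s: float = 4.0   # strictly greater than 4 s
    baseline_window_s: float = 120.0      # excursion baseline (pre-event)

    # -- steps 4-5: event scoring ------------------------------------------
    apnea_excursion_fraction: float = 0.3162  # sqrt(0.10): 90% pressure drop
    hypopnea_excursion_fraction: float = 0.70  # 30% airflow drop
    min_event_duration_s: float = 10.0    # AASM 2012 minimum
    max_event_duration_s: float = 180.0   # sensor-displacement guard
    confirm_window_s: float = 60.0        # 1-min pre/post confirmation window
    apnea_confirm_drop: float = 0.20      # confirmation-channel drop, apneas
    hypopnea_confirm_drop: float = 0.10   # confirmation-channel drop, hypopneas
    attempt_significance: float = 0.10    # RIP attempt vs 1-min baseline
    snore_power_ratio: float = 2.0        # insp/exp audio power for snoring
    ifl_seed: int = 42                    # IFL network training seed
    ifl_enabled: bool = True

    # -- step 6 + bench -----------------------------------------------------
    lung_compliance_ml: float = 80.0      # C, mL/cmH2O
    lung_resistance: float = 7.25         # R, cmH2O/(L/s)
    starling_pus: float = 4.0             # upstream pressure, cmH2O
    starling_rus: float = 4.0             # upstream resistance, cmH2O/(L/s)
    starling_pch_max: float = 10.0        # top of the control range, cmH2O
    regulator_tau_s: float = 0.3          # chamber-pressure regulator lag
    transition_artifact: bool = False     # emulate tube-collapse flow spike
    # config hook for the two future flow-limitation variants; only the
    # default mode is implemented.
    ifl_simulation_mode: str = "default"  # {default, obstructive, open}

    # -- evaluation ---------------------------------------------------------
    match_tolerance_s: float = 1.5        # cycle-pairing onset tolerance
    min_cycle_samples: int = 40           # per-cycle Pearson r requirement
    apnea_overlap_fraction: float = 0.5   # event matching overlap

    # -- io -----------------------------------------------------------------
    channel_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    seed: int = 0

    # ----------------------------------------------------------------------
    def validate(self) -> None:
        for name in (
            "fs", "savgol_window_s", "slope_ratio", "reduced_min_duration_s",
            "min_event_duration_s", "max_event_duration_s",
            "lung_compliance_ml", "starling_pus",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        if not 0 < self.apnea_excursion_fraction < self.hypopnea_excursion_fraction < 1:
            raise ValueError("apnea fraction must be below hypopnea fraction, both in (0,1)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg
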