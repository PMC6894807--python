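"""Polygraph ingestion and signal preprocessing (step 1).

Reads an EDF polygraph recording, harmonizes every channel onto the common
20 Hz analysis timebase, applies Savitzky–Golay smoothing, and derives the
estimated nasal airflow ``vsource`` as the signed square root of nasal
pressure — the conventional linearization of a nasal-cannula pressure signal.

All series produced here live on the half-open 20 Hz sample grid
``[0, n)``; times are seconds from recording start.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal

from .config import DEFAULT_CHANNEL_MAP, PipelineConfig
from .errors import ConfigurationError

log = logging.getLogger(__name__)

#: roles that must resolve for the pipeline to run
MANDATORY_ROLES = (
    "accel_norm", "nasal_pressure", "rip_thorax", "rip_abdomen",
    "rip_flow", "audio",
)
#: channels smoothed by the Savitzky-Golay filter after downsampling
SMOOTHED_ROLES = (
    "nasal_pressure", "rip_flow", "rip_thorax", "rip_abdomen", "audio",
)


@dataclass
class Channel:
    data: np.ndarray
    rate: float  # Hz


@dataclass
class PolygraphRecord:
    """A multichannel recording plus, after :func:`preprocess`, the derived
    20 Hz series used by every downstream step.

    ``channels`` holds the as-read series keyed by canonical role;
    ``series`` holds the 20 Hz versions, and ``vsource`` the estimated nasal
    airflow (present only after preprocessing, finite everywhere).
    """

    channels: dict[str, Channel]
    channel_map: dict[str, str] = field(default_factory=dict)
    fs: float = 20.0
    series: dict[str, np.ndarray] = field(default_factory=dict)
    vsource: np.ndarray | None = None

    @property
    def duration_s(self) -> float:
        if self.series:
            return len(next(iter(self.series.values()))) / self.fs
        ch = next(iter(self.channels.values()))
        return len(ch.data) / ch.rate

    @property
    def n_samples(self) -> int:
        if not self.series:
            raise ValueError("record not preprocessed")
        return len(next(iter(self.series.values())))

    def to_csv(self, path: str | Path) -> None:
        """Columnar 20 Hz dump of the preprocessed channels for inspection."""
        import pandas as pd

        if self.vsource is None:
            raise ValueError("preprocess the record before exporting")
        cols = {"t_s": np.arange(self.n_samples) / self.fs}
        cols.update({k: v for k, v in sorted(self.series.items())})
        cols["vsource"] = self.vsource
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def load_polygraph(
    path: str | Path,
    channel_map: dict[str, str] | None = None,
) -> PolygraphRecord:
    """Read an EDF file and attach channels under their canonical roles.

    ``channel_map`` maps role -> recording channel name (defaults match the
    synthetic writer / Nox-style labels).  Three separate accelerometer axes
    (roles ``accel_x/y/z``) are collapsed to their Euclidean norm.  A missing
    mandatory channel raises :class:`ConfigurationError` naming the role.
    """
    import mne

    channel_map = dict(channel_map or DEFAULT_CHANNEL_MAP)
    path = Path(path)
    if not path.exists():
        raise IOError(f"EDF file not found: {path}")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - corrupt file branch
        raise IOError(f"unreadable EDF file {path}: {exc}") from exc
    rate = float(raw.info["sfreq"])
    data = raw.get_data()
    by_name = {name: data[i] for i, name in enumerate(raw.ch_names)}

    channels: dict[str, Channel] = {}
    for role, name in channel_map.items():
        if name in by_name:
            channels[role] = Channel(np.asarray(by_name[name], float), rate)

    if "accel_norm" not in channels:
        axes = [channels.pop(f"accel_{ax}", None) for ax in "xyz"]
        if all(a is not None for a in axes):
            norm = np.sqrt(sum(a.data ** 2 for a in axes))
            channels["accel_norm"] = Channel(norm, axes[0].rate)
    for role in MANDATORY_ROLES:
        if role not in channels:
            raise ConfigurationError(
                f"mandatory channel role {role!r} not found in {path.name} "
                f"(mapped name: {channel_map.get(role)!r})")
    return PolygraphRecord(channels=channels, channel_map=channel_map)


def resample_to_20hz(
    series: np.ndarray, native_rate: float, fs: float = 20.0,
) -> np.ndarray:
    """Bring a series to the 20 Hz timebase.

    Downsampling uses a zero-phase polyphase FIR (anti-aliasing before
    decimation), so breath onsets are not phase-shifted.  Rates below 20 Hz
    (e.g. 3 Hz SpO2) are upsampled by sample-and-hold and flagged in the log.
    Output length is ``floor(duration * fs)``.
    """
    series = np.asarray(series, dtype=float)
    n_out = math.floor(len(series) / native_rate * fs)
    if native_rate == fs:
        return series[:n_out].copy()
    if native_rate < fs:
        log.warning(
            "upsampling %.3g Hz channel to %.3g Hz by sample-and-hold", native_rate, fs)
        idx = np.minimum(
            (np.arange(n_out) * native_rate / fs).astype(int), len(series) - 1)
        return series[idx]
    frac = Fraction(fs / native_rate).limit_denominator(10_000)
    # linear boundary extension avoids the zero-padding edge transient
    out = signal.resample_poly(series, frac.numerator, frac.denominator,
                               padtype="line")
    return out[:n_out]


def savgol_smooth(
    series: np.ndarray, fs: float = 20.0,
    window_s: float = 1.0, order: int = 3,
) -> np.ndarray:
    """Savitzky–Golay smoothing: 1 s window (forced odd: 21 samples at
    20 Hz), third-degree polynomial.  Series shorter than the window are
    returned unchanged with a warning."""
    series = np.asarray(series, dtype=float)
    window = int(round(window_s * fs))
    if window % 2 == 0:
        window += 1
    if len(series) < window:
        log.warning("series of %d samples shorter than %d-sample smoothing "
                    "window; returned unchanged", len(series), window)
        return series.copy()
    return signal.savgol_filter(series, window, order)


def nasal_pressure_to_flow(pressure: np.ndarray) -> np.ndarray:
    """Signed square-root transform of the (zero-centred) nasal pressure.

    ``sign(p) * sqrt(|p|)`` preserves inspiratory/expiratory polarity; the
    plain square root is only defined for a rectified signal.  Under this
    transform a 90% pressure reduction becomes a ``1 - sqrt(0.1) = 68.4%``
    airflow reduction.
    """
    pressure = np.asarray(pressure, dtype=float)
    return np.sign(pressure) * np.sqrt(np.abs(pressure))


def preprocess(
    record: PolygraphRecord, config: PipelineConfig | None = None,
) -> PolygraphRecord:
    """Run step 1 on a loaded record: resample, smooth, derive ``vsource``.

    Channels below 20 Hz (SpO2) are carried as metadata only; nothing
    downstream consumes them.  All derived series are truncated to a common
    length.
    """
    config = config or PipelineConfig()
    fs = config.fs
    out: dict[str, np.ndarray] = {}
    for role in MANDATORY_ROLES:
        ch = record.channels[role]
        s = resample_to_20hz(ch.data, ch.rate, fs)
        if role in SMOOTHED_ROLES:
            s = savgol_smooth(s, fs, config.savgol_window_s, config.savgol_order)
        out[role] = s
    if "thermistance" in record.channels:
        ch = record.channels["thermistance"]
        s = resample_to_20hz(ch.data, ch.rate, fs)
        out["thermistance"] = savgol_smooth(
            s, fs, config.savgol_window_s, config.savgol_order)

    n = min(len(s) for s in out.values())
    out = {k: v[:n] for k, v in out.items()}
    out["accel_norm"] = np.abs(out["accel_norm"])

    record.series = out
    record.fs = fs
    record.vsource = nasal_pressure_to_flow(out["nasal_pressure"])
    if not np.all(np.isfinite(record.vsource)):
        raise ValueError("non-finite samples in derived nasal airflow")
    return record
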