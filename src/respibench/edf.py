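"""Minimal writer for the European Data Format (EDF).

Only writing is implemented here (reading goes through :mod:`mne`, see
:mod:`respibench.io_polygraph`): the environment offers no EDF export, and the
synthetic-night generator needs to produce standard files so the reader is
exercised end-to-end.  The writer emits plain 16-bit EDF with one-second data
records, which any polygraphy tool can open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_HEADER_DATE = "01.01.20"
_HEADER_TIME = "00.00.00"


def _field(text: str, width: int) -> bytes:
    raw = text.encode("ascii")
    if len(raw) > width:
        raise ValueError(f"EDF header field too long: {text!r} > {width}")
    return raw.ljust(width)


def _num8(v: float) -> str:
    """Shortest decimal representation of ``v`` fitting the 8-byte header
    fields."""
    for prec in (6, 5, 4, 3, 2, 1):
        s = f"{v:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{v:.0e}"[:8]


def write_edf(
    path: str | Path,
    signals: list[tuple[str, float, np.ndarray]],
    *,
    record_duration_s: float = 1.0,
    patient: str = "X X X X",
    recording: str = "Startdate 01-JAN-2020 X X X",
) -> None:
    """Write ``signals`` — a list of ``(label, rate_hz, data)`` — as 16-bit EDF.

    Each signal's physical range is taken from its data (symmetric, with a
    small margin so the digital grid never clips).  ``rate_hz *
    record_duration_s`` must be a whole number of samples for every signal;
    with one-second records any integer rate works.  Trailing samples that do
    not fill a complete record are dropped, as the format requires.
    """
    if not signals:
        raise ValueError("no signals to write")
    per_record = []
    for label, rate, _ in signals:
        n = rate * record_duration_s
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError(
                f"rate {rate} Hz of {label!r} does not fill {record_duration_s} s records")
        per_record.append(int(round(n)))
    n_records = min(
        int(len(d) // n) for (_, _, d), n in zip(signals, per_record))
    ns = len(signals)

    header = b""
    header += _field("0", 8)                           # version
    header += _field(patient, 80)
    header += _field(recording, 80)
    header += _field(_HEADER_DATE, 8)
    header += _field(_HEADER_TIME, 8)
    header += _field(str(256 * (ns + 1)), 8)           # header bytes
    header += _field("", 44)                           # reserved
    header += _field(str(n_records), 8)
    header += _field(f"{record_duration_s:g}", 8)
    header += _field(str(ns), 4)

    phys_min, phys_max, scaled = [], [], []
    for _, _, data in signals:
        data = np.asarray(data, dtype=float)
        span = float(np.max(np.abs(data))) if data.size else 1.0
        span = max(span * 1.01, 1e-6)
        # scale with the value as it will be read back from the header
        span = float(_num8(span))
        phys_min.append(-span)
        phys_max.append(span)
        dig = np.round(data / span * 32767.0)
        scaled.append(np.clip(dig, -32768, 32767).astype("<i2"))

    def block(values, width):
        return b"".join(_field(str(v), width) for v in values)

    header += block([s[0] for s in signals], 16)       # labels
    header += block([""] * ns, 80)                     # transducer
    header += block([""] * ns, 8)                      # physical dimension
    header += block([_num8(v) for v in phys_min], 8)
    header += block([_num8(v) for v in phys_max], 8)
    header += block([-32768] * ns, 8)                  # digital min
    header += block([32767] * ns, 8)                   # digital max
    header += block([""] * ns, 80)                     # prefiltering
    header += block(per_record, 8)                     # samples per record
    header += block([""] * ns, 32)                     # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for dig, n in zip(scaled, per_record):
                fh.write(dig[rec * n:(rec + 1) * n].tobytes())
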