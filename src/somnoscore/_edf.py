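"""Minimal plain-EDF (16-bit European Data Format) writer.

Writes the classic EDF dialect: one header, equal-length 1-second data
records, all channels sampled at the same rate, physical unit microvolts.
Reading is delegated to :mod:`mne` elsewhere in the package; this writer
exists so that synthetic recordings can round-trip through the standard
container format.
"""

from __future__ import annotations

import datetime as _dt
import math
import os

import numpy as np

_DIG_MIN = -32768
_DIG_MAX = 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} ascii characters")
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | os.PathLike,
    signals: np.ndarray,
    sample_rate_hz: float,
    channel_names: list[str],
    subject_id: str = "X",
    physical_range_uv: float | None = None,
    start_time: _dt.datetime | None = None,
) -> None:
    """Write ``signals`` (n_channels x n_samples, microvolts) as plain EDF.

    The recording length must be a whole number of seconds and the sample
    rate a positive integer, because the writer emits 1-second data records.
    ``physical_range_uv`` sets the symmetric physical min/max; by default it
    is chosen just above the data's absolute maximum. Amplitudes outside the
    declared range raise rather than clip.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2:
        raise ValueError("signals must be a 2-D (n_channels, n_samples) array")
    n_channels, n_samples = signals.shape
    if n_channels != len(channel_names):
        raise ValueError("one channel name per signal row is required")
    rate = float(sample_rate_hz)
    if rate <= 0 or abs(rate - round(rate)) > 1e-9:
        raise ValueError("sample_rate_hz must be a positive integer for EDF 1-s records")
    rate = int(round(rate))
    if n_samples % rate != 0:
        raise ValueError(
            f"recording length ({n_samples} samples) must be a whole number of "
            f"seconds at {rate} Hz"
        )
    n_records = n_samples // rate

    peak = float(np.max(np.abs(signals))) if signals.size else 0.0
    if physical_range_uv is None:
        physical_range_uv = max(math.ceil(peak) + 1.0, 1.0)
    if peak > physical_range_uv:
        raise ValueError(
            f"signal amplitude {peak:.1f} uV exceeds declared physical range "
            f"+/-{physical_range_uv:.1f} uV"
        )
    pmin, pmax = -float(physical_range_uv), float(physical_range_uv)

    # EDF digital-to-physical mapping: p = pmin + (d - dmin) * (pmax-pmin)/(dmax-dmin)
    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((signals - pmin) / scale + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    t0 = start_time or _dt.datetime(2000, 1, 1, 0, 0, 0)
    header_bytes = 256 + 256 * n_channels

    head = b""
    head += _field("0", 8)                                   # version
    head += _field(subject_id, 80)                           # patient id
    head += _field("recording", 80)                          # recording id
    head += _field(t0.strftime("%d.%m.%y"), 8)
    head += _field(t0.strftime("%H.%M.%S"), 8)
    head += _field(str(header_bytes), 8)
    head += _field("", 44)                                   # reserved
    head += _field(str(n_records), 8)
    head += _field("1", 8)                                   # record duration, s
    head += _field(str(n_channels), 4)

    for name in channel_names:
        head += _field(name, 16)
    head += _field("", 80) * n_channels                      # transducer
    head += _field("uV", 8) * n_channels
    for _ in channel_names:
        head += _field(f"{pmin:.1f}", 8)
    for _ in channel_names:
        head += _field(f"{pmax:.1f}", 8)
    head += _field(str(_DIG_MIN), 8) * n_channels
    head += _field(str(_DIG_MAX), 8) * n_channels
    head += _field("", 80) * n_channels                      # prefiltering
    head += _field(str(rate), 8) * n_channels                # samples per record
    head += _field("", 32) * n_channels                      # reserved

    assert len(head) == header_bytes

    # Data records: for each second, each channel's block of `rate` samples.
    blocks = digital.reshape(n_channels, n_records, rate)
    interleaved = np.ascontiguousarray(blocks.transpose(1, 0, 2))

    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(interleaved.tobytes())


def quantization_step_uv(physical_range_uv: float) -> float:
    """Size of one 16-bit digital step for a symmetric physical range."""
    return 2.0 * physical_range_uv / (_DIG_MAX - _DIG_MIN)
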