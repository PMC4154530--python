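"""Recordings, hypnograms and 30-second epoching.

The scoring unit throughout the package is the 30-s epoch: a two-channel
block of forehead EEG (FP1, FP2 at 128 Hz gives 3840 samples per channel)
paired with one sleep-stage label. Recordings travel as plain EDF files,
labels as a small `epoch,stage` CSV side-car written by a separate manual
scoring workflow.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import _edf

logger = logging.getLogger(__name__)

EPOCH_DURATION_S = 30.0


class SleepStage(str, Enum):
    """The five AASM sleep stages plus UNKNOWN for unscored epochs."""

    W = "W"
    N1 = "N1"
    N2 = "N2"
    N3 = "N3"
    REM = "REM"
    UNKNOWN = "?"

    @classmethod
    def parse(cls, token: str) -> "SleepStage":
        token = token.strip()
        if token == "?":
            return cls.UNKNOWN
        try:
            return cls[token]
        except KeyError:
            raise ValueError(f"unrecognized sleep stage token {token!r}") from None


#: Fixed stage order used by every multiclass model and confusion matrix.
STAGE_ORDER: tuple[SleepStage, ...] = (
    SleepStage.W,
    SleepStage.N1,
    SleepStage.N2,
    SleepStage.N3,
    SleepStage.REM,
)


@dataclass
class Recording:
    """A subject's multi-channel EEG in microvolts.

    ``signals`` has shape (n_channels, n_samples); all channels share one
    sample rate, as in a single-device forehead montage.
    """

    subject_id: str
    channel_names: list[str]
    sample_rate_hz: float
    signals: np.ndarray
    start_time: object | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (n_channels, n_samples)")
        if self.signals.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match signal rows")
        if not self.channel_names:
            raise ValueError("at least one channel required")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.signals.shape[1] / self.sample_rate_hz


@dataclass
class Hypnogram:
    """One sleep-stage label per 30-s epoch, in temporal order."""

    stages: list[SleepStage]
    epoch_duration_s: float = EPOCH_DURATION_S

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise ValueError("hypnogram must contain at least one epoch")
        if self.epoch_duration_s <= 0:
            raise ValueError("epoch_duration_s must be positive")
        self.stages = [SleepStage(s) for s in self.stages]

    def __len__(self) -> int:
        return len(self.stages)


@dataclass
class EpochSignal:
    """One 30-s two-channel signal block, the atomic scoring unit."""

    channels: np.ndarray  # (2, n) microvolts
    sample_rate_hz: float
    epoch_index: int = 0

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        expected = int(round(EPOCH_DURATION_S * self.sample_rate_hz))
        if self.channels.shape[1] != expected:
            raise ValueError(
                f"epoch must hold exactly {expected} samples per channel at "
                f"{self.sample_rate_hz} Hz, got {self.channels.shape[1]}"
            )
        if self.epoch_index < 0:
            raise ValueError("epoch_index must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]


# ---------------------------------------------------------------------------
# EDF I/O


def write_edf(
    recording: Recording,
    path: str | os.PathLike,
    physical_range_uv: float | None = None,
) -> None:
    """Write a recording as plain 16-bit EDF (physical unit microvolts)."""
    _edf.write_edf(
        path,
        recording.signals,
        recording.sample_rate_hz,
        recording.channel_names,
        subject_id=recording.subject_id,
        physical_range_uv=physical_range_uv,
        start_time=recording.start_time,
    )


def read_edf(path: str | os.PathLike, channels: list[str] | None = None) -> Recording:
    """Read an EDF recording, returning signals in microvolts.

    ``channels`` selects and orders the channels (e.g. ``["FP1", "FP2"]``);
    a requested channel missing from the file raises. EDF digital-to-physical
    scaling is applied by the reader.
    """
    import mne

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    available = list(raw.ch_names)
    if channels is not None:
        missing = [c for c in channels if c not in available]
        if missing:
            raise ValueError(
                f"channel(s) {missing} not present in {path} (has {available})"
            )
        raw = raw.pick(channels)
        names = list(channels)
    else:
        names = available
    data_uv = raw.get_data() * 1e6  # mne returns volts
    subject = (raw.info.get("subject_info") or {}).get("his_id", "") or os.path.splitext(
        os.path.basename(path)
    )[0]
    return Recording(
        subject_id=subject,
        channel_names=names,
        sample_rate_hz=float(raw.info["sfreq"]),
        signals=data_uv,
        start_time=raw.info.get("meas_date"),
    )


# ---------------------------------------------------------------------------
# Hypnogram I/O


def write_hypnogram(hypnogram: Hypnogram, path: str | os.PathLike) -> None:
    """Write the `epoch,stage` CSV side-car (stages uppercase, `?` unknown)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("epoch,stage\n")
        for i, stage in enumerate(hypnogram.stages):
            fh.write(f"{i},{stage.value}\n")


def read_hypnogram(path: str | os.PathLike) -> Hypnogram:
    """Read a hypnogram side-car file.

    Accepts the two-column `epoch,stage` CSV this package writes, or a bare
    one-token-per-line format. Unrecognized tokens and duplicate epoch
    indices raise with the offending line number.
    """
    stages: dict[int, SleepStage] = {}
    plain: list[SleepStage] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh]
    body = [ln for ln in lines if ln]
    if not body:
        raise ValueError(f"empty hypnogram file: {path}")
    has_header = body[0].lower().replace(" ", "") == "epoch,stage"
    for lineno, ln in enumerate(body, start=1):
        if lineno == 1 and has_header:
            continue
        try:
            if "," in ln:
                idx_s, tok = ln.split(",", 1)
                idx = int(idx_s)
                if idx in stages:
                    raise ValueError(f"duplicate epoch index {idx}")
                stages[idx] = SleepStage.parse(tok)
            else:
                plain.append(SleepStage.parse(ln))
        except ValueError as exc:
            raise ValueError(f"{path}, line {lineno}: {exc}") from None
    if stages and plain:
        raise ValueError(f"{path}: mixed CSV and plain-token lines")
    if stages:
        if sorted(stages) != list(range(len(stages))):
            raise ValueError(f"{path}: epoch indices must be contiguous from 0")
        ordered = [stages[i] for i in range(len(stages))]
    else:
        ordered = plain
    return Hypnogram(stages=ordered)


# ---------------------------------------------------------------------------
# Epoching


def segment_epochs(
    recording: Recording,
    hypnogram: Hypnogram | None = None,
    max_length_mismatch: int | None = None,
) -> list[tuple[EpochSignal, SleepStage]]:
    """Cut a recording into consecutive, non-overlapping 30-s epochs.

    A trailing partial block is discarded (with a log message). When a
    hypnogram is supplied, epoch i is paired with label i (both starting at
    the recording start); if the two disagree in length, the excess on
    either side is dropped with a warning, unless the difference exceeds
    ``max_length_mismatch`` epochs, which raises.
    """
    n_per_epoch = int(round(EPOCH_DURATION_S * recording.sample_rate_hz))
    n_total = recording.signals.shape[1]
    n_epochs = n_total // n_per_epoch
    if n_epochs < 1:
        raise ValueError(
            f"recording of {recording.duration_s:.1f} s is shorter than one "
            f"{EPOCH_DURATION_S:.0f}-s epoch"
        )
    leftover = n_total - n_epochs * n_per_epoch
    if leftover:
        logger.info(
            "discarding trailing partial epoch (%.1f s) of subject %s",
            leftover / recording.sample_rate_hz,
            recording.subject_id,
        )

    if hypnogram is None:
        labels = [SleepStage.UNKNOWN] * n_epochs
        n_keep = n_epochs
    else:
        mismatch = abs(len(hypnogram) - n_epochs)
        if max_length_mismatch is not None and mismatch > max_length_mismatch:
            raise ValueError(
                f"hypnogram has {len(hypnogram)} labels but recording has "
                f"{n_epochs} epochs (mismatch {mismatch} > tolerance "
                f"{max_length_mismatch})"
            )
        if mismatch:
            logger.warning(
                "hypnogram (%d) and recording (%d epochs) lengths differ; "
                "truncating to the shorter",
                len(hypnogram),
                n_epochs,
            )
        n_keep = min(n_epochs, len(hypnogram))
        labels = hypnogram.stages[:n_keep]

    out: list[tuple[EpochSignal, SleepStage]] = []
    for i in range(n_keep):
        block = recording.signals[:, i * n_per_epoch : (i + 1) * n_per_epoch]
        out.append(
            (
                EpochSignal(
                    channels=block,
                    sample_rate_hz=recording.sample_rate_hz,
                    epoch_index=i,
                ),
                labels[i],
            )
        )
    return out
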