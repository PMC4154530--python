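"""Seeded synthetic two-channel sleep-EEG generator.

Real overnight forehead recordings cannot be shipped with the package, so
this module synthesizes stage-labeled 30-s epochs whose *spectral* content
realizes the visual scoring rules the feature extractor targets:

* W   — alpha (8–12 Hz) rhythm over more than half of the epoch, some beta;
* N1  — low-amplitude theta (5–7 Hz) rhythm over more than half the epoch;
* N2  — theta background plus sleep spindles (12–14 Hz bursts of 0.5–1.5 s)
        and K-complexes (large biphasic transients >= 0.5 s), each arriving
        about once every two epochs;
* N3  — high-amplitude slow-wave activity (sub-2 Hz, > 75 uV) occupying
        more than 20% of the epoch;
* REM — theta background with large slow eye-movement deflections that are
        anti-correlated between the two frontopolar channels.

Each epoch is a sum of band-limited Gaussian noise carriers (the dominant
rhythm gated to its occupancy window with raised-cosine edges), transient
events with raised-cosine envelopes shared across channels, and a per-channel
1/f + white noise floor. The two channels share rhythms and events, as the
near-symmetric FP1/FP2 sites do, and differ only by independent noise (and by
the sign of eye movements). Stage prevalences default to the typical
overnight distribution W 18.4%, N1 13.1%, N2 37.8%, N3 15.6%, REM 15.1%.

All randomness flows from one master seed through fixed per-subject
substreams (``numpy.random.SeedSequence(seed).spawn``), so a cohort is
reproducible bit-for-bit from its seed alone.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .io import (
    EPOCH_DURATION_S,
    STAGE_ORDER,
    EpochSignal,
    Hypnogram,
    Recording,
    SleepStage,
    write_edf,
    write_hypnogram,
)

DEFAULT_SAMPLE_RATE_HZ = 128.0

#: Overnight stage prevalences used as the simulator's default mixture.
DEFAULT_PREVALENCE: dict[SleepStage, float] = {
    SleepStage.W: 0.184,
    SleepStage.N1: 0.131,
    SleepStage.N2: 0.378,
    SleepStage.N3: 0.156,
    SleepStage.REM: 0.151,
}


@dataclass(frozen=True)
class EventSpec:
    """A transient event class: spindle, K-complex, slow wave or eye movement."""

    kind: str  # {spindle, k_complex, slow_wave, eye_movement}
    rate_per_epoch: float
    duration_s: tuple[float, float]
    amplitude_uv: float
    freq_hz: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("spindle", "k_complex", "slow_wave", "eye_movement"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        lo, hi = self.duration_s
        if not (0 < lo <= hi <= EPOCH_DURATION_S):
            raise ValueError("event durations must lie in (0, 30] s")
        if self.rate_per_epoch < 0 or self.amplitude_uv < 0:
            raise ValueError("rate and amplitude must be non-negative")


@dataclass(frozen=True)
class StageRecipe:
    """Spectral construction rules for one sleep stage.

    ``dominant_band`` (Hz) is a band-noise carrier of RMS
    ``dominant_rms_uv`` gated to a contiguous window covering
    ``occupancy_fraction`` of the epoch; ``background_bands`` are continuous
    (low_hz, high_hz, rms_uv) carriers; ``events`` are inserted at random
    onsets. ``pink_rms_uv``/``white_rms_uv`` set the per-channel noise floor.
    """

    stage: SleepStage
    dominant_band: tuple[float, float]
    dominant_rms_uv: float
    occupancy_fraction: float
    background_bands: tuple[tuple[float, float, float], ...] = ()
    events: tuple[EventSpec, ...] = ()
    pink_rms_uv: float = 8.0
    white_rms_uv: float = 3.0
    #: epoch-to-epoch spread around the nominal occupancy; visual scoring
    #: thresholds (">50% of the epoch") sit inside this spread, so epochs
    #: near stage boundaries genuinely overlap
    occupancy_jitter: float = 0.15
    #: SD of the per-epoch log amplitude jitter of the dominant rhythm
    amplitude_jitter_sd: float = 0.3
    #: nonstationary part of the noise floor: brief broadband bursts
    #: (frontalis EMG / movement artifacts, present in unedited forehead
    #: recordings in every stage); sorted segment statistics are robust to
    #: them, whole-epoch spectra are not
    burst_rate_per_epoch: float = 4.0
    burst_rms_uv: float = 25.0
    burst_duration_s: tuple[float, float] = (0.3, 1.5)

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy_fraction <= 1.0:
            raise ValueError("occupancy_fraction must be in [0, 1]")
        if self.dominant_rms_uv < 0:
            raise ValueError("relative powers must be >= 0")


def default_recipes() -> dict[SleepStage, StageRecipe]:
    """The five default stage recipes (amplitudes in microvolts RMS)."""
    return {
        SleepStage.W: StageRecipe(
            stage=SleepStage.W,
            dominant_band=(8.0, 12.0),
            dominant_rms_uv=12.0,
            occupancy_fraction=0.60,
            background_bands=((15.0, 30.0, 5.0), (5.0, 7.0, 4.0)),
        ),
        SleepStage.N1: StageRecipe(
            stage=SleepStage.N1,
            dominant_band=(5.0, 7.0),
            dominant_rms_uv=10.0,
            occupancy_fraction=0.60,
            # alpha attenuated but not absent at sleep onset
            background_bands=((8.0, 12.0, 4.0),),
        ),
        SleepStage.N2: StageRecipe(
            stage=SleepStage.N2,
            dominant_band=(5.0, 7.0),
            dominant_rms_uv=10.0,
            occupancy_fraction=0.55,
            events=(
                # spindles and K-complexes each arrive about every 2 epochs
                EventSpec("spindle", 0.5, (0.5, 1.5), 20.0, (12.0, 14.0)),
                EventSpec("k_complex", 0.5, (0.5, 1.0), 75.0),
            ),
        ),
        SleepStage.N3: StageRecipe(
            stage=SleepStage.N3,
            dominant_band=(0.75, 2.0),
            dominant_rms_uv=50.0,  # peaks above the 75-uV slow-wave bar
            occupancy_fraction=0.35,
            background_bands=((5.0, 7.0, 7.0),),
        ),
        SleepStage.REM: StageRecipe(
            stage=SleepStage.REM,
            dominant_band=(5.0, 7.0),
            dominant_rms_uv=10.0,
            occupancy_fraction=0.60,
            events=(
                # rapid-eye-movement deflections; rate is a free parameter
                EventSpec("eye_movement", 3.0, (0.5, 1.5), 50.0),
            ),
        ),
    }


@dataclass
class SimulationConfig:
    n_subjects: int = 10
    epochs_per_subject: int = 300
    stage_prevalence: dict[SleepStage, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    recipes: dict[SleepStage, StageRecipe] = field(default_factory=default_recipes)
    inter_subject_variability: float = 0.2  # SD of log amplitude gain
    stickiness: float = 0.0  # P(repeat previous stage); marginal stays the prevalence
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.stage_prevalence.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"stage prevalences must sum to 1 (got {total})")
        if any(p < 0 for p in self.stage_prevalence.values()):
            raise ValueError("prevalences must be non-negative")
        if not 0.0 <= self.stickiness < 1.0:
            raise ValueError("stickiness must be in [0, 1)")


# ---------------------------------------------------------------------------
# Signal building blocks


def _band_noise(rng, n: int, fs: float, low: float, high: float, rms: float):
    """Gaussian noise band-limited to [low, high] Hz with the target RMS."""
    spec = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < low) | (f > high)] = 0.0
    x = np.fft.irfft(spec, n)
    cur = np.sqrt(np.mean(x * x))
    return x * (rms / cur) if cur > 0 else x


def _pink_noise(rng, n: int, fs: float, rms: float):
    """1/f-amplitude noise (flat below 0.5 Hz to keep power finite)."""
    spec = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(f, 0.5))
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    cur = np.sqrt(np.mean(x * x))
    return x * (rms / cur) if cur > 0 else x


def _raised_cosine_gate(n: int, start: int, length: int, edge: int) -> np.ndarray:
    """A 0/1 gate with raised-cosine ramps of ``edge`` samples."""
    g = np.zeros(n)
    end = min(start + length, n)
    g[start:end] = 1.0
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
    if start + edge <= n:
        g[start : start + edge] = np.minimum(g[start : start + edge], ramp)
    if end - edge >= 0:
        g[end - edge : end] = np.minimum(g[end - edge : end], ramp[::-1])
    return g


def _event_waveform(spec: EventSpec, fs: float, rng) -> np.ndarray:
    dur = float(rng.uniform(*spec.duration_s))
    n = max(int(round(dur * fs)), 4)
    t = np.arange(n) / fs
    env = np.sin(np.pi * np.arange(n) / (n - 1)) ** 2  # Hann^1... raised cosine
    if spec.kind == "spindle":
        f = float(rng.uniform(*spec.freq_hz))
        phase = float(rng.uniform(0, 2 * np.pi))
        return spec.amplitude_uv * env * np.sin(2 * np.pi * f * t + phase)
    if spec.kind == "k_complex":
        # negative sharp wave immediately followed by a positive component
        return -spec.amplitude_uv * env * np.sin(2 * np.pi * t / dur)
    if spec.kind == "slow_wave":
        f = float(rng.uniform(*spec.freq_hz)) if spec.freq_hz[1] > 0 else 1.0
        return spec.amplitude_uv * env * np.sin(2 * np.pi * f * t)
    if spec.kind == "eye_movement":
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return sign * spec.amplitude_uv * env
    raise ValueError(spec.kind)


def simulate_epoch(
    recipe: StageRecipe,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    rng: np.random.Generator | None = None,
    n_channels: int = 2,
    amplitude_gain: float = 1.0,
) -> EpochSignal:
    """Synthesize one stage-labeled 30-s epoch.

    ``amplitude_gain`` is the subject-level multiplicative jitter; the
    per-segment PSD normalization in the feature extractor is designed to
    cancel exactly this kind of between-subject amplitude difference.
    """
    rng = rng or np.random.default_rng()
    fs = sample_rate_hz
    n = int(round(EPOCH_DURATION_S * fs))

    common = np.zeros(n)
    # dominant rhythm over its occupancy window; occupancy and amplitude
    # jitter epoch to epoch so epochs near scoring thresholds overlap
    occupancy = float(
        np.clip(
            recipe.occupancy_fraction
            + rng.uniform(-recipe.occupancy_jitter, recipe.occupancy_jitter),
            0.0,
            1.0,
        )
    )
    rms = recipe.dominant_rms_uv * float(
        np.exp(rng.normal(0.0, recipe.amplitude_jitter_sd))
    )
    if rms > 0 and occupancy > 0:
        length = int(round(occupancy * n))
        start = int(rng.integers(0, n - length + 1)) if length < n else 0
        gate = _raised_cosine_gate(n, start, length, edge=int(0.25 * fs))
        carrier = _band_noise(
            rng, n, fs, recipe.dominant_band[0], recipe.dominant_band[1], rms
        )
        common += gate * carrier
    for low, high, rms in recipe.background_bands:
        common += _band_noise(rng, n, fs, low, high, rms)

    # broadband artifact bursts: amplitude-modulated noise-floor transients
    for _ in range(int(rng.poisson(recipe.burst_rate_per_epoch))):
        dur = float(rng.uniform(*recipe.burst_duration_s))
        m = max(int(round(dur * fs)), 4)
        onset = int(rng.integers(0, n - m + 1))
        env = np.sin(np.pi * np.arange(m) / (m - 1)) ** 2
        burst_rms = recipe.burst_rms_uv * float(np.exp(rng.normal(0.0, 0.4)))
        common[onset : onset + m] += env * _band_noise(
            rng, m, fs, 0.5, min(50.0, fs / 2 - 1e-6), burst_rms
        )

    # events shared across channels (eye movements flip sign on channel 2)
    eye = np.zeros(n)
    for ev in recipe.events:
        for _ in range(int(rng.poisson(ev.rate_per_epoch))):
            wf = _event_waveform(ev, fs, rng)
            if wf.size > n:
                raise ValueError(f"event duration exceeds the epoch ({ev.kind})")
            onset = int(rng.integers(0, n - wf.size + 1))
            target = eye if ev.kind == "eye_movement" else common
            target[onset : onset + wf.size] += wf

    channels = np.empty((n_channels, n))
    for c in range(n_channels):
        floor = _pink_noise(rng, n, fs, recipe.pink_rms_uv) + rng.normal(
            0.0, recipe.white_rms_uv, n
        )
        em_sign = 1.0 if c == 0 else -1.0  # anti-correlated frontal eye movements
        channels[c] = amplitude_gain * (common + em_sign * eye + floor)
    return EpochSignal(channels=channels, sample_rate_hz=fs, epoch_index=0)


# ---------------------------------------------------------------------------
# Subjects and cohorts


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    """Fixed master-seed -> per-subject substream derivation."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(subject_index,))
    )


def _draw_stages(config: SimulationConfig, rng) -> list[SleepStage]:
    stages = [s for s in STAGE_ORDER]
    p = np.array([config.stage_prevalence[s] for s in stages])
    p = p / p.sum()
    out: list[SleepStage] = []
    for i in range(config.epochs_per_subject):
        if out and rng.random() < config.stickiness:
            out.append(out[-1])  # sticky repeat; stationary marginal unchanged
        else:
            out.append(stages[int(rng.choice(len(stages), p=p))])
    return out


def simulate_subject(
    config: SimulationConfig, subject_index: int
) -> tuple[Recording, Hypnogram]:
    """One subject's night: a stage sequence realized epoch by epoch."""
    if config.epochs_per_subject < 1:
        raise ValueError("epochs_per_subject must be >= 1")
    rng = _subject_rng(config.seed, subject_index)
    gain = float(np.exp(rng.normal(0.0, config.inter_subject_variability)))
    stage_seq = _draw_stages(config, rng)
    n = int(round(EPOCH_DURATION_S * config.sample_rate_hz))
    signals = np.empty((2, n * len(stage_seq)))
    for i, stage in enumerate(stage_seq):
        ep = simulate_epoch(
            config.recipes[stage],
            sample_rate_hz=config.sample_rate_hz,
            rng=rng,
            amplitude_gain=gain,
        )
        signals[:, i * n : (i + 1) * n] = ep.channels
    rec = Recording(
        subject_id=f"S{subject_index + 1:02d}",
        channel_names=["FP1", "FP2"],
        sample_rate_hz=config.sample_rate_hz,
        signals=signals,
    )
    return rec, Hypnogram(stages=stage_seq)


def simulate_cohort(
    config: SimulationConfig, out_dir: str | os.PathLike | None = None
) -> list[tuple[Recording, Hypnogram]]:
    """Simulate ``config.n_subjects`` independent subjects.

    With ``out_dir`` set, each subject is written as ``<id>.edf`` plus
    ``<id>.hypnogram.csv`` and a ``manifest.json`` recording the seed and
    sizes, so a cohort on disk is traceable to its configuration.
    """
    if config.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    cohort = [simulate_subject(config, i) for i in range(config.n_subjects)]
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        manifest = {
            "seed": config.seed,
            "n_subjects": config.n_subjects,
            "epochs_per_subject": config.epochs_per_subject,
            "sample_rate_hz": config.sample_rate_hz,
            "subjects": [],
        }
        for rec, hyp in cohort:
            edf_path = os.path.join(out_dir, f"{rec.subject_id}.edf")
            hyp_path = os.path.join(out_dir, f"{rec.subject_id}.hypnogram.csv")
            write_edf(rec, edf_path)
            write_hypnogram(hyp, hyp_path)
            manifest["subjects"].append(
                {"id": rec.subject_id, "edf": edf_path, "hypnogram": hyp_path}
            )
        with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
    return cohort
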