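"""Knowledge-based STFT features and the conventional whole-epoch PSD baseline.

The knowledge-based extractor mirrors how a sleep technician scores a 30-s
epoch: instead of one Fourier transform over the whole epoch (which smears a
0.5–1.5-s spindle or K-complex into the background), the epoch is cut into
59 half-overlapping 1-s segments (1-s Hamming window, 0.5-s step), each
segment's power spectrum is normalized to unit total power (removing
absolute-amplitude individual differences), and per-band statistics over the
59 segments encode the visual scoring rules:

=============  ==========  ==============================================
band           Hz          statistics (per channel)
=============  ==========  ==============================================
lower delta    1–2         mean of upper 80%, mean of lower 80%  (slow waves)
delta          1–4         max, mean of remaining 58             (K-complex)
theta          5–7         mean of upper 50%, lower 50%          (light sleep)
alpha          8–12        mean of upper 50%, lower 50%          (wake)
sigma          12–14       max, mean of remaining 58             (spindle)
beta           15–30       mean of upper 50%, lower 50%          (wake)
gamma          30–50       mean of all 59                        (movement)
=============  ==========  ==============================================

giving 13 features per channel, 26 for FP1+FP2. The conventional baseline is
the whole-epoch periodogram aggregated into 50 one-Hz bands centered at
1..50 Hz and normalized to unit sum per channel (100 features for two
channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .io import EpochSignal


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band; edges are inclusive when summing bins."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: low_hz must be < high_hz")


#: Default band set. The lower-delta edge follows the 1-Hz STFT bin grid
#: (1–2 Hz); an alternative 0.5-Hz lower edge can be configured but falls
#: between bins at 1-s window length.
DEFAULT_BANDS: dict[str, BandDefinition] = {
    b.name: b
    for b in (
        BandDefinition("lower_delta", 1.0, 2.0),
        BandDefinition("delta", 1.0, 4.0),
        BandDefinition("theta", 5.0, 7.0),
        BandDefinition("alpha", 8.0, 12.0),
        BandDefinition("sigma", 12.0, 14.0),
        BandDefinition("beta", 15.0, 30.0),
        BandDefinition("gamma", 30.0, 50.0),
    )
}


@dataclass
class SegmentSpectrogram:
    """Per-segment one-sided PSD of one channel (n_segments x n_bins)."""

    psd: np.ndarray
    bin_freqs_hz: np.ndarray
    normalized: bool = False

    @property
    def n_segments(self) -> int:
        return self.psd.shape[0]


@dataclass
class FeatureVector:
    """A named, fixed-length real feature vector for one epoch."""

    values: np.ndarray
    schema: list[str]
    channel_names: list[str] = field(default_factory=lambda: ["FP1", "FP2"])

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.schema),):
            raise ValueError("values length must equal schema length")


def stft_psd(
    channel_signal: np.ndarray,
    sample_rate_hz: float,
    window_s: float = 1.0,
    step_s: float = 0.5,
) -> SegmentSpectrogram:
    """Hamming-windowed per-segment periodograms of one channel.

    Segment count is floor((L - W) / S) + 1 for signal/window/step lengths
    L, W, S in samples; a 30-s epoch at 128 Hz with the default 1-s window
    and 0.5-s step yields 59 segments. The PSD is the one-sided density
    periodogram of each windowed segment, not yet normalized.
    """
    x = np.asarray(channel_signal, dtype=float).ravel()
    nper = int(round(window_s * sample_rate_hz))
    step = int(round(step_s * sample_rate_hz))
    if abs(nper - window_s * sample_rate_hz) > 1e-9:
        raise ValueError("window_s x sample_rate_hz must be an integer sample count")
    if x.size < nper:
        raise ValueError(f"signal ({x.size} samples) shorter than window ({nper})")
    freqs, _, psd = sps.spectrogram(
        x,
        fs=sample_rate_hz,
        window=sps.get_window("hamming", nper),
        nperseg=nper,
        noverlap=nper - step,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    return SegmentSpectrogram(psd=psd.T.copy(), bin_freqs_hz=freqs, normalized=False)


def normalize_segments(spec: SegmentSpectrogram) -> SegmentSpectrogram:
    """Divide each segment's PSD by its total power so rows sum to 1.

    This is the step that removes inter-individual amplitude differences:
    every later feature is a power *proportion*. An all-zero segment has no
    defined proportion and raises.
    """
    if spec.normalized:
        raise ValueError("spectrogram is already normalized")
    totals = spec.psd.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        bad = int(np.flatnonzero(totals.ravel() <= 0)[0])
        raise ValueError(f"segment {bad} has zero total power (degenerate input)")
    return SegmentSpectrogram(
        psd=spec.psd / totals, bin_freqs_hz=spec.bin_freqs_hz, normalized=True
    )


def band_power_series(spec: SegmentSpectrogram, band: BandDefinition) -> np.ndarray:
    """Per-segment summed normalized power within a band (edges inclusive)."""
    if not spec.normalized:
        raise ValueError("band_power_series requires a normalized spectrogram")
    f = spec.bin_freqs_hz
    if band.low_hz < f[0] - 1e-9 or band.high_hz > f[-1] + 1e-9:
        raise ValueError(
            f"band {band.name} ({band.low_hz}-{band.high_hz} Hz) outside "
            f"available bins ({f[0]}-{f[-1]} Hz)"
        )
    mask = (f >= band.low_hz - 1e-9) & (f <= band.high_hz + 1e-9)
    return spec.psd[:, mask].sum(axis=1)


def sorted_fraction_mean(values: np.ndarray, fraction: float, which: str) -> float:
    """Mean of the top (``which='upper'``) or bottom (``'lower'``) fraction.

    Values are sorted and the first k = max(1, floor(fraction * n)) taken.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if which not in ("upper", "lower"):
        raise ValueError("which must be 'upper' or 'lower'")
    k = max(1, int(np.floor(fraction * v.size)))
    v = np.sort(v)
    return float(v[-k:].mean() if which == "upper" else v[:k].mean())


def max_and_rest_mean(values: np.ndarray) -> tuple[float, float]:
    """The maximum and the mean of all values but one occurrence of it."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    i = int(np.argmax(v))
    rest = np.delete(v, i)
    return float(v[i]), float(rest.mean())


# feature recipe: (band, statistic) in fixed schema order, 13 per channel
_KNOWLEDGE_RECIPE: tuple[tuple[str, str], ...] = (
    ("lower_delta", "upper80_mean"),
    ("lower_delta", "lower80_mean"),
    ("delta", "max"),
    ("delta", "rest_mean"),
    ("theta", "upper50_mean"),
    ("theta", "lower50_mean"),
    ("alpha", "upper50_mean"),
    ("alpha", "lower50_mean"),
    ("sigma", "max"),
    ("sigma", "rest_mean"),
    ("beta", "upper50_mean"),
    ("beta", "lower50_mean"),
    ("gamma", "mean"),
)

KNOWLEDGE_FEATURES_PER_CHANNEL = len(_KNOWLEDGE_RECIPE)


def _stat(series: np.ndarray, stat: str) -> float:
    if stat == "upper80_mean":
        return sorted_fraction_mean(series, 0.8, "upper")
    if stat == "lower80_mean":
        return sorted_fraction_mean(series, 0.8, "lower")
    if stat == "upper50_mean":
        return sorted_fraction_mean(series, 0.5, "upper")
    if stat == "lower50_mean":
        return sorted_fraction_mean(series, 0.5, "lower")
    if stat == "max":
        return max_and_rest_mean(series)[0]
    if stat == "rest_mean":
        return max_and_rest_mean(series)[1]
    if stat == "mean":
        return float(np.mean(series))
    raise ValueError(f"unknown statistic {stat!r}")


def extract_knowledge_features(
    epoch: EpochSignal,
    bands: dict[str, BandDefinition] | None = None,
    window_s: float = 1.0,
    step_s: float = 0.5,
    channel_names: list[str] | None = None,
) -> FeatureVector:
    """The 13-per-channel knowledge-based feature vector (26 for FP1+FP2).

    All values are normalized power proportions in [0, 1]; scaling the raw
    epoch by any positive constant leaves the vector unchanged.
    """
    bands = bands or DEFAULT_BANDS
    names = channel_names or [f"ch{c}" for c in range(epoch.n_channels)]
    if epoch.n_channels == 2 and channel_names is None:
        names = ["FP1", "FP2"]
    values: list[float] = []
    schema: list[str] = []
    for ci in range(epoch.n_channels):
        spec = normalize_segments(
            stft_psd(epoch.channels[ci], epoch.sample_rate_hz, window_s, step_s)
        )
        series = {
            name: band_power_series(spec, band) for name, band in bands.items()
        }
        for band_name, stat in _KNOWLEDGE_RECIPE:
            values.append(_stat(series[band_name], stat))
            schema.append(f"{names[ci]}.{band_name}.{stat}")
    return FeatureVector(values=np.array(values), schema=schema, channel_names=names)


def extract_conventional_features(
    epoch: EpochSignal,
    low_hz: float = 1.0,
    high_hz: float = 50.0,
    normalize: bool = True,
    channel_names: list[str] | None = None,
) -> FeatureVector:
    """Whole-epoch PSD baseline: 50 one-Hz bands (1..50 Hz) per channel.

    The epoch-long periodogram is aggregated into one-Hz bands centered at
    integer frequencies; with ``normalize`` (default) each channel's 50
    values are divided by their sum, making the baseline scale-invariant
    like the knowledge features.
    """
    names = channel_names or [f"ch{c}" for c in range(epoch.n_channels)]
    if epoch.n_channels == 2 and channel_names is None:
        names = ["FP1", "FP2"]
    centers = np.arange(int(low_hz), int(high_hz) + 1)
    values: list[float] = []
    schema: list[str] = []
    for ci in range(epoch.n_channels):
        freqs, psd = sps.periodogram(
            epoch.channels[ci],
            fs=epoch.sample_rate_hz,
            window="hamming",
            detrend=False,
            scaling="density",
        )
        bandpow = np.empty(centers.size)
        for j, c in enumerate(centers):
            mask = (freqs >= c - 0.5) & (freqs < c + 0.5)
            bandpow[j] = psd[mask].sum()
        total = bandpow.sum()
        if total <= 0:
            raise ValueError("zero-power epoch")
        if normalize:
            bandpow = bandpow / total
        values.extend(bandpow.tolist())
        schema.extend(f"{names[ci]}.psd_{c}hz" for c in centers)
    return FeatureVector(values=np.array(values), schema=schema, channel_names=names)
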