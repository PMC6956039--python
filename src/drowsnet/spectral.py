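"""Spectral analyses: band power by state/level, in-band mean frequency, and
paired statistical comparisons with optional Bonferroni correction.

The PSD estimator is the mean periodogram over 1-s epochs (equivalently,
Welch's method with rectangular 1-s segments), giving 1 Hz resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import EpochSet, LabelScheme
from .train_eval import paired_ttest

__all__ = [
    "BandDef",
    "DEFAULT_BANDS",
    "welch_psd",
    "band_power_by_class",
    "mean_frequency",
    "band_compare",
    "SpectralTable",
]


@dataclass(frozen=True)
class BandDef:
    """A frequency band, half-open [low, high)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: need low < high")


DEFAULT_BANDS = [
    BandDef("delta", 1.0, 4.0),
    BandDef("theta", 4.0, 8.0),
    BandDef("alpha", 8.0, 13.0),
    BandDef("beta", 13.0, 30.0),
    BandDef("gamma", 30.0, 50.0),
]


def welch_psd(epochs: EpochSet, channel: int | str) -> tuple[np.ndarray, np.ndarray]:
    """Epoch-averaged power spectral density of one channel.

    Uses a full-epoch rectangular window per 1-s epoch, averaged across
    epochs, so the integrated spectrum matches the mean time-domain variance
    (Parseval).
    """
    if len(epochs) < 1:
        raise ValueError("no epochs selected")
    if isinstance(channel, str):
        channel = epochs.channel_labels.index(channel)
    x = epochs.epochs[:, channel, :]
    freqs, pxx = sps.periodogram(x, fs=epochs.fs, window="boxcar", detrend="constant", axis=-1)
    return freqs, pxx.mean(axis=0)


@dataclass
class SpectralTable:
    """Per (class, channel, band) mean power; rows keyed by class name."""

    class_names: list[str]
    channel_labels: list[str]
    band_names: list[str]
    power: np.ndarray  # (n_classes, n_channels, n_bands)

    def to_records(self) -> list[dict]:
        rec = []
        for ci, cname in enumerate(self.class_names):
            for chi, ch in enumerate(self.channel_labels):
                for bi, band in enumerate(self.band_names):
                    rec.append({"class": cname, "channel": ch, "band": band,
                                "power": float(self.power[ci, chi, bi])})
        return rec


def band_power_by_class(epochs: EpochSet, scheme: LabelScheme,
                        bands: list[BandDef] | None = None) -> SpectralTable:
    """Mean per-channel band power for every class of the label scheme.

    This is the numeric substrate of a band-power scalp topography.
    """
    bands = bands if bands is not None else DEFAULT_BANDS
    y = epochs.labels(scheme)
    present = np.unique(y)
    missing = [scheme.class_names[c] for c in range(scheme.n_classes) if c not in present]
    if missing:
        raise ValueError(f"no epochs for class(es) {missing}")
    x = epochs.epochs
    freqs, pxx = sps.periodogram(x, fs=epochs.fs, window="boxcar", detrend="constant", axis=-1)
    n_ch = x.shape[1]
    power = np.empty((scheme.n_classes, n_ch, len(bands)))
    for cls in range(scheme.n_classes):
        mean_pxx = pxx[y == cls].mean(axis=0)  # (channels, freqs)
        for bi, band in enumerate(bands):
            sel = (freqs >= band.low) & (freqs < band.high)
            power[cls, :, bi] = mean_pxx[:, sel].sum(axis=-1)
    labels = epochs.channel_labels or [f"ch{i}" for i in range(n_ch)]
    return SpectralTable(
        class_names=list(scheme.class_names),
        channel_labels=list(labels),
        band_names=[b.name for b in bands],
        power=power,
    )


def mean_frequency(epochs: EpochSet, band: BandDef, channel: int | str | None = None) -> float:
    """Power-weighted spectral centroid restricted to a band (Hz).

    With ``channel=None`` the centroid is computed per channel and then
    averaged.  Raises if the in-band power is zero.
    """
    if band.low >= epochs.fs / 2.0:
        raise ValueError(f"band {band.name} lies beyond Nyquist {epochs.fs / 2.0} Hz")
    if channel is not None:
        freqs, psd = welch_psd(epochs, channel)
        psds = [psd]
    else:
        psds = []
        freqs = None
        for ch in range(epochs.epochs.shape[1]):
            freqs, psd = welch_psd(epochs, ch)
            psds.append(psd)
    sel = (freqs >= band.low) & (freqs < band.high)
    centroids = []
    for psd in psds:
        total = psd[sel].sum()
        if total <= 0:
            raise ValueError(f"zero in-band power for band {band.name}")
        centroids.append(float((freqs[sel] * psd[sel]).sum() / total))
    return float(np.mean(centroids))


def band_compare(table_a: np.ndarray, table_b: np.ndarray,
                 correction: str = "bonferroni") -> np.ndarray:
    """Paired t-tests between two paired observation stacks.

    ``table_a`` and ``table_b`` are (n_pairs, ...) arrays of per-pair means
    (for example per-subject band power, shaped (n_subjects, channels,
    bands)).  Returns the two-sided p-value for every trailing cell;
    Bonferroni multiplies each p by the number of cells (capped at 1).
    """
    a = np.asarray(table_a, dtype=float)
    b = np.asarray(table_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired tables must have identical shapes")
    if a.shape[0] < 2:
        raise ValueError("at least 2 pairs are required")
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    cell_shape = a.shape[1:]
    m = int(np.prod(cell_shape)) if cell_shape else 1
    a2 = a.reshape(a.shape[0], m)
    b2 = b.reshape(b.shape[0], m)
    pvals = np.empty(m)
    for j in range(m):
        _, p = paired_ttest(a2[:, j], b2[:, j], zero_variance="one")
        pvals[j] = p
    if correction == "bonferroni":
        pvals = np.minimum(pvals * m, 1.0)
    return pvals.reshape(cell_shape) if cell_shape else pvals[0]
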